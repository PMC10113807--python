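"""Delay embedding and simplex projection against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecoreservoir.embedding import (embed, knn_search, loo_simplex_skill,
                                    select_embedding_dimension,
                                    simplex_forecast, simplex_state_update)


def brute_force_knn(library, labels, query, k, exclude=frozenset()):
    """Independent exhaustive neighbour search (sorted by distance, label)."""
    rows = [(float(np.sqrt(np.sum((lib - query) ** 2))), int(lab), i)
            for i, (lib, lab) in enumerate(zip(library, labels))
            if i not in exclude]
    rows.sort(key=lambda r: (r[0], r[1]))
    return [r[2] for r in rows[:k]], [r[0] for r in rows[:k]]


def brute_force_simplex(library, labels, targets, query, E,
                        exclude=frozenset()):
    """Independent weighted-average forecast computation."""
    ids, dists = brute_force_knn(library, labels, query, E + 1, exclude)
    d = np.asarray(dists)
    if d[0] == 0.0:
        w = (d == 0.0).astype(float)
    else:
        w = np.exp(-d / d[0])
    w = w / w.sum()
    return float(np.dot(w, [targets[i] for i in ids]))


class TestEmbed:
    def test_enumerated_rows_e2(self):
        e = embed([1, 2, 3, 4, 5], E=2, tau=1)
        np.testing.assert_array_equal(e.library, [[2, 1], [3, 2], [4, 3]])
        np.testing.assert_array_equal(e.targets, [3, 4, 5])
        np.testing.assert_array_equal(e.time_labels, [1, 2, 3])

    def test_identity_embedding_e1(self):
        e = embed([1, 2, 3, 4, 5], E=1, tau=1)
        np.testing.assert_array_equal(e.library.ravel(), [1, 2, 3, 4])
        np.testing.assert_array_equal(e.targets, [2, 3, 4, 5])

    def test_row_count_and_lag_structure_e3_tau2(self):
        x = np.arange(10.0) ** 2
        e = embed(x, E=3, tau=2)
        assert e.n_rows == 10 - 1 - 4 == 5
        # hand enumeration: row at label t is (x_t, x_{t-2}, x_{t-4}) -> x_{t+1}
        for row, lab, tgt in zip(e.library, e.time_labels, e.targets):
            np.testing.assert_array_equal(row, [x[lab], x[lab - 2], x[lab - 4]])
            assert tgt == x[lab + 1]

    @given(n=st.integers(5, 60), E=st.integers(1, 4), tau=st.integers(1, 3))
    @settings(max_examples=60, deadline=None)
    def test_row_count_formula_and_coordinate_recovery(self, n, E, tau):
        rng = np.random.default_rng(n * 100 + E * 10 + tau)
        x = rng.normal(size=n)
        expected = n - 1 - (E - 1) * tau
        if expected < 1:
            with pytest.raises(ValueError, match="insufficient length"):
                embed(x, E, tau)
            return
        e = embed(x, E, tau)
        assert e.n_rows == expected
        # coordinate 1 of library rows reproduces x[(E-1)tau .. n-2]
        np.testing.assert_array_equal(e.library[:, 0], x[(E - 1) * tau: n - 1])

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="invalid series"):
            embed([1.0, np.nan, 2.0, 3.0], E=1, tau=1)


class TestKnn:
    def test_exact_row_query_distance_zero(self, logistic_embedding):
        q = logistic_embedding.library[10]
        ids, d = knn_search(logistic_embedding, q, k=1)
        assert ids[0] == 10 and d[0] == 0.0

    def test_excluding_exact_match_returns_next(self, logistic_embedding):
        q = logistic_embedding.library[10]
        ids, d = knn_search(logistic_embedding, q, k=1, exclude={10})
        assert ids[0] != 10 and d[0] > 0.0

    def test_k_too_large_raises(self, logistic_embedding):
        with pytest.raises(ValueError, match="not enough neighbours"):
            knn_search(logistic_embedding, logistic_embedding.library[0],
                       k=logistic_embedding.n_rows + 1)

    @given(st.integers(0, 999))
    @settings(max_examples=1000, deadline=None)
    def test_agrees_with_exhaustive_search(self, case):
        rng = np.random.default_rng(case)
        n = int(rng.integers(8, 50))
        E = int(rng.integers(1, 4))
        x = rng.normal(size=n + E + 1)
        e = embed(x, E, 1)
        q = rng.normal(size=E)
        k = int(rng.integers(1, e.n_rows + 1))
        exclude = set(rng.choice(e.n_rows, size=min(2, e.n_rows - k),
                                 replace=False).tolist()) \
            if e.n_rows - k >= 1 else set()
        ids, d = knn_search(e, q, k, exclude)
        bids, bd = brute_force_knn(e.library, e.time_labels, q, k, exclude)
        assert list(ids) == bids
        np.testing.assert_allclose(d, bd, atol=1e-12)


class TestSimplexForecast:
    def test_constant_series_predicts_constant(self):
        e = embed([5.0] * 30, E=2, tau=1)
        assert simplex_forecast(e, [5.0, 5.0]) == pytest.approx(5.0)

    def test_exact_unique_row_returns_its_target(self, logistic_embedding):
        q = logistic_embedding.library[17]
        pred = simplex_forecast(logistic_embedding, q)
        assert pred == pytest.approx(logistic_embedding.targets[17], abs=1e-12)

    def test_matches_brute_force_on_logistic_map(self, logistic_series):
        e = embed(logistic_series[:30], E=2, tau=1)
        rng = np.random.default_rng(3)
        for _ in range(50):
            q = e.library[rng.integers(e.n_rows)] + rng.normal(0, 0.01, 2)
            expected = brute_force_simplex(e.library, e.time_labels,
                                           e.targets, q, e.E)
            assert simplex_forecast(e, q) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 400))
    @settings(max_examples=400, deadline=None)
    def test_brute_force_agreement_random_instances(self, case):
        rng = np.random.default_rng(10_000 + case)
        n = int(rng.integers(10, 50))
        E = int(rng.integers(1, 4))
        x = rng.normal(size=n + E + 1)
        e = embed(x, E, 1)
        q = rng.normal(size=E)
        expected = brute_force_simplex(e.library, e.time_labels, e.targets,
                                       q, E)
        assert simplex_forecast(e, q) == pytest.approx(expected, abs=1e-12)

    def test_prediction_within_neighbour_target_range(self, logistic_embedding):
        rng = np.random.default_rng(8)
        for _ in range(30):
            q = rng.uniform(0, 1, 2)
            ids, _ = knn_search(logistic_embedding, q,
                                logistic_embedding.E + 1)
            pred = simplex_forecast(logistic_embedding, q)
            tg = logistic_embedding.targets[ids]
            assert tg.min() - 1e-12 <= pred <= tg.max() + 1e-12

    def test_library_too_small(self):
        e = embed([1.0, 2.0, 1.5, 2.5], E=3, tau=1)  # single row
        with pytest.raises(ValueError, match="library too small"):
            simplex_forecast(e, [1.0, 1.0, 1.0])


class TestSimplexStateUpdate:
    def test_shift_property(self, logistic_series):
        e = embed(logistic_series, E=3, tau=1)
        state = np.array([0.3, 0.6, 0.9])
        new = simplex_state_update(e, state)
        np.testing.assert_array_equal(new[1:], state[:-1])

    def test_constant_library_fixed_point(self):
        e = embed([2.0] * 40, E=3, tau=1)
        state = np.array([2.0, 2.0, 2.0])
        np.testing.assert_allclose(simplex_state_update(e, state), state)

    def test_period_two_cycle_advances(self):
        x = np.array([1.0, 3.0] * 30)
        e = embed(x, E=2, tau=1)
        on_cycle = np.array([3.0, 1.0])
        new = simplex_state_update(e, on_cycle)
        # next on-cycle state: forecast of (3,1) is 1, shift gives (1,3)
        np.testing.assert_allclose(new, [1.0, 3.0], atol=1e-12)


class TestEmbeddingSelection:
    def test_logistic_map_prefers_low_dimension(self, logistic_series):
        E_star, skills = select_embedding_dimension(logistic_series, E_max=10)
        assert E_star <= 3
        assert skills[E_star] > 0.99

    def test_white_noise_has_no_skill(self):
        x = np.random.default_rng(0).normal(size=200)
        _, skills = select_embedding_dimension(x, E_max=5)
        assert max(abs(s) for s in skills.values()) < 0.2

    def test_deterministic(self, logistic_series):
        a = select_embedding_dimension(logistic_series, E_max=6)
        b = select_embedding_dimension(logistic_series, E_max=6)
        assert a[0] == b[0] and a[1] == b[1]

    def test_loo_skill_matches_per_row_exclusion(self, logistic_series):
        """The vectorised leave-one-out path equals row-by-row exclusion."""
        x = logistic_series[:60]
        e = embed(x, E=2, tau=1)
        preds = [simplex_forecast(e, e.library[i], exclude={i})
                 for i in range(e.n_rows)]
        expected = float(np.corrcoef(preds, e.targets)[0, 1])
        assert loo_simplex_skill(x, 2) == pytest.approx(expected, abs=1e-12)
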