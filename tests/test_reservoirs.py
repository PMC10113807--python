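"""Reservoir dynamics: simplex reservoir, LV toy map, ESN, multiplexing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecoreservoir.embedding import embed
from ecoreservoir.reservoirs import (EcoReservoir, LvParams, StateTrajectory,
                                     erc_run, erc_step, esn_init, esn_run,
                                     lv_map_step, lv_reservoir_run,
                                     make_input_weights, multiplex_states)
from ecoreservoir.tasks import gen_lorenz


class TestInputWeights:
    def test_zero_sparsity_entries_within_scale(self):
        w = make_input_weights(50, 4, scale=0.3, sparsity=0.0, seed=1)
        assert np.all(np.abs(w.matrix) <= 0.3)
        assert not np.any(w.matrix == 0.0)

    def test_full_sparsity_all_zero(self):
        w = make_input_weights(10, 3, scale=0.3, sparsity=1.0, seed=1)
        assert np.all(w.matrix == 0.0)

    @given(st.floats(0.0, 1.0), st.integers(0, 50))
    @settings(max_examples=40, deadline=None)
    def test_exact_zero_count(self, sparsity, seed):
        w = make_input_weights(12, 5, scale=0.5, sparsity=sparsity, seed=seed)
        assert (w.matrix == 0.0).sum() == round(sparsity * 60)

    def test_seed_reproducibility(self):
        a = make_input_weights(8, 2, seed=7).matrix
        b = make_input_weights(8, 2, seed=7).matrix
        np.testing.assert_array_equal(a, b)


class TestErcStep:
    @pytest.fixture()
    def reservoir(self, logistic_series):
        emb = embed(logistic_series, E=3, tau=1)
        w = make_input_weights(3, 1, scale=0.3, seed=2)
        return emb, w

    def test_zero_input_equals_pure_simplex_update(self, reservoir):
        from ecoreservoir.embedding import simplex_state_update
        emb, w = reservoir
        for variant in ("project_then_add", "add_then_project"):
            r = EcoReservoir(embedding=emb, w_in=w, variant=variant)
            state0 = r.state.copy()
            new = erc_step(r, 0.0)
            np.testing.assert_allclose(new, simplex_state_update(emb, state0))

    def test_zero_weights_variants_identical(self, reservoir):
        emb, _ = reservoir
        w0 = make_input_weights(3, 1, sparsity=1.0, seed=0)
        ra = EcoReservoir(embedding=emb, w_in=w0, variant="project_then_add")
        rb = EcoReservoir(embedding=emb, w_in=w0, variant="add_then_project")
        np.testing.assert_allclose(erc_step(ra, 1.7), erc_step(rb, 1.7))

    def test_manual_arithmetic_small_library(self):
        """One step on an 8-row library checked against hand computation."""
        x = np.array([0.1, 0.9, 0.2, 0.8, 0.3, 0.7, 0.4, 0.6, 0.5, 0.45])
        emb = embed(x, E=2, tau=1)  # 8 rows
        w = make_input_weights(2, 1, scale=0.3, seed=5)
        r = EcoReservoir(embedding=emb, w_in=w, variant="project_then_add")
        state = np.array([0.55, 0.35])
        r.state = state.copy()
        # hand computation: nearest 3 rows, exponential weights, then shift+add
        d = np.sqrt(np.sum((emb.library - state) ** 2, axis=1))
        order = np.argsort(d, kind="stable")[:3]
        wts = np.exp(-d[order] / d[order[0]])
        wts /= wts.sum()
        pred = float(wts @ emb.targets[order])
        expected = w.matrix[:, 0] * 2.0 + np.array([pred, 0.55])
        np.testing.assert_allclose(erc_step(r, 2.0), expected, atol=1e-12)

    def test_constant_library_translation_linearity(self):
        """With a constant-series library the update is forecast-constant,
        so state responds linearly (by translation) to W_in u."""
        emb = embed([1.0] * 50, E=2, tau=1)
        w = make_input_weights(2, 1, scale=0.3, seed=3)
        out = {}
        for u in (0.0, 1.0, 2.0):
            r = EcoReservoir(embedding=emb, w_in=w)
            r.state = np.array([1.0, 1.0])
            out[u] = erc_step(r, u)
        np.testing.assert_allclose(out[2.0] - out[1.0], out[1.0] - out[0.0],
                                   atol=1e-12)


class TestErcRun:
    def test_empty_input_gives_empty_trajectory(self, logistic_series):
        emb = embed(logistic_series, E=2, tau=1)
        r = EcoReservoir(embedding=emb,
                         w_in=make_input_weights(2, 1, seed=0))
        traj = erc_run(r, np.empty((0, 1)))
        assert traj.T == 0

    def test_constant_library_zero_input_constant_trajectory(self):
        emb = embed([2.0] * 60, E=2, tau=1)
        r = EcoReservoir(embedding=emb,
                         w_in=make_input_weights(2, 1, seed=1))
        traj = erc_run(r, np.zeros(20), init_state=[2.0, 2.0])
        np.testing.assert_allclose(traj.matrix, 2.0)

    def test_rows_are_post_input_states(self, logistic_series):
        emb = embed(logistic_series, E=2, tau=1)
        w = make_input_weights(2, 1, seed=4)
        r1 = EcoReservoir(embedding=emb, w_in=w)
        u = np.array([0.1, 0.2, 0.3])
        traj = erc_run(r1, u)
        r2 = EcoReservoir(embedding=emb, w_in=w)
        for t in range(3):
            s = erc_step(r2, u[t])
            np.testing.assert_allclose(traj.matrix[t], s)


class TestMultiplex:
    def test_single_trajectory_unchanged(self):
        t = StateTrajectory(matrix=np.arange(12.0).reshape(4, 3))
        np.testing.assert_array_equal(multiplex_states([t]).matrix, t.matrix)

    def test_column_counts_add(self):
        a = StateTrajectory(matrix=np.zeros((5, 3)))
        b = StateTrajectory(matrix=np.ones((5, 4)))
        assert multiplex_states([a, b]).state_dim == 7

    def test_concatenation_offsets(self):
        """Column j of species s appears at offset sum_{i<s} E_i + j."""
        rng = np.random.default_rng(0)
        dims = [3, 1, 5, 2]
        trajs = [StateTrajectory(matrix=rng.normal(size=(6, d)))
                 for d in dims]
        m = multiplex_states(trajs).matrix
        off = 0
        for tr, d in zip(trajs, dims):
            np.testing.assert_array_equal(m[:, off:off + d], tr.matrix)
            off += d

    def test_many_trajectories_running_sum(self):
        rng = np.random.default_rng(1)
        dims = rng.integers(1, 9, size=500)
        trajs = [StateTrajectory(matrix=np.zeros((3, d))) for d in dims]
        assert multiplex_states(trajs).state_dim == dims.sum()

    def test_mismatched_lengths_raise(self):
        a = StateTrajectory(matrix=np.zeros((5, 2)))
        b = StateTrajectory(matrix=np.zeros((6, 2)))
        with pytest.raises(ValueError, match="mismatched"):
            multiplex_states([a, b])


class TestLvMap:
    def test_origin_fixed_point(self):
        np.testing.assert_array_equal(
            lv_map_step([0.0, 0.0], LvParams()), [0.0, 0.0])

    def test_reduces_to_logistic_when_alone(self):
        p = LvParams(r_x=2.0, r_y=2.7, beta_xy=0.0, beta_yx=0.0)
        out = lv_map_step([0.5, 0.0], p)
        assert out[0] == pytest.approx(2.0 * 0.5 * 0.5)  # logistic r=2 at 0.5
        assert out[1] == 0.0

    def test_extinction_absorbing(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = rng.uniform(0, 1)
            out = lv_map_step([0.0, y], LvParams())
            assert out[0] == 0.0

    def test_three_iterates_from_half_half(self):
        """Direct iteration fixture at the standard parameter values."""
        s = np.array([0.5, 0.5])
        p = LvParams()  # r_x=3.0, r_y=2.7, beta_xy=-0.2, beta_yx=0.2
        seq = []
        for _ in range(3):
            s = lv_map_step(s, p)
            seq.append(s.copy())
        # hand-iterated: x1 = .5(3 - 1.5 - .1) = .7; y1 = .5(2.7 - 1.35 + .1) = .725
        np.testing.assert_allclose(seq[0], [0.7, 0.725], atol=1e-12)
        x2 = 0.7 * (3 - 3 * 0.7 - 0.2 * 0.725)
        y2 = 0.725 * (2.7 - 2.7 * 0.725 + 0.2 * 0.7)
        np.testing.assert_allclose(seq[1], [x2, y2], atol=1e-12)


class TestLvReservoir:
    def test_zero_everything_stays_zero(self):
        w = make_input_weights(2, 1, sparsity=1.0, seed=0)
        traj = lv_reservoir_run(LvParams(), w, np.zeros(10), init=(0.0, 0.0))
        np.testing.assert_array_equal(traj.matrix, 0.0)

    def test_zero_weights_pure_orbit(self):
        w = make_input_weights(2, 1, sparsity=1.0, seed=0)
        traj = lv_reservoir_run(LvParams(), w, np.zeros(30), init=(0.5, 0.5))
        s = np.array([0.5, 0.5])
        for t in range(30):
            s = lv_map_step(s, LvParams())
            np.testing.assert_allclose(traj.matrix[t], s)

    def test_bounded_under_scaled_lorenz_input(self):
        lo = gen_lorenz(n=1000, dt=0.01, subsample=5, zscore=False)
        u = ((lo.u - lo.u.min()) / (lo.u.max() - lo.u.min()) - 0.5) * 0.6
        w = make_input_weights(2, 1, scale=0.3, seed=3)
        traj = lv_reservoir_run(LvParams(), w, u)
        assert np.all(np.abs(traj.matrix) < 10.0)
        assert traj.state_dim == 2


class TestEsn:
    def test_single_unit_full_density(self):
        r = esn_init(1, 1, spectral_radius=0.7, density=1.0, seed=0)
        assert abs(abs(r.W[0, 0]) - 0.7) < 1e-12

    def test_spectral_radius_rescaled(self):
        r = esn_init(80, 1, spectral_radius=0.9, density=0.1, seed=2)
        radius = np.max(np.abs(np.linalg.eigvals(r.W)))
        assert radius == pytest.approx(0.9, abs=1e-8)

    def test_seed_reproducibility(self):
        a = esn_init(30, 2, seed=5)
        b = esn_init(30, 2, seed=5)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.w_in.matrix, b.w_in.matrix)

    def test_tanh_states_bounded(self):
        r = esn_init(40, 1, spectral_radius=1.2, density=0.3, seed=1)
        u = np.random.default_rng(0).normal(size=200) * 3
        traj = esn_run(r, u)
        assert np.all(np.abs(traj.matrix) < 1.0)

    def test_contraction_below_unit_radius(self):
        """Two different initial states converge under the same input."""
        r = esn_init(60, 1, spectral_radius=0.5, density=0.2, seed=4)
        u = np.random.default_rng(1).uniform(0, 1, 100)
        rng = np.random.default_rng(2)
        ta = esn_run(r, u, init=rng.normal(size=60))
        tb = esn_run(r, u, init=rng.normal(size=60))
        d = np.linalg.norm(ta.matrix - tb.matrix, axis=1)
        assert d[-1] < 1e-6
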