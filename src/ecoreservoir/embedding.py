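"""Time-delay embedding and simplex projection.

State-space reconstruction (Takens-type embedding) turns a single observed
time series into a library of lagged coordinate vectors; simplex projection
forecasts the next value of a query state as the distance-weighted average
of the next-step values of its ``E + 1`` nearest library neighbours.  These
two primitives are the engine behind the simplex-projection reservoir: the
reconstructed attractor plays the role of a fixed, untrained dynamical
system whose response to perturbed states can be simulated ("scenario
exploration").

Conventions
-----------
* Library rows are "most recent coordinate first": the row with time label
  ``t`` is ``(x_t, x_{t-tau}, ..., x_{t-(E-1)tau})`` and its target is
  ``x_{t+1}``.
* Distances are unweighted Euclidean; ties are broken by the smaller time
  label so every search is reproducible.
* Simplex weights are ``w_i = exp(-d_i / d_min)`` normalised to sum to one;
  when the nearest distance is exactly zero the zero-distance neighbours
  share uniform weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

__all__ = [
    "DelayEmbedding",
    "embed",
    "knn_search",
    "simplex_forecast",
    "simplex_state_update",
    "select_embedding_dimension",
]


@dataclass(frozen=True)
class DelayEmbedding:
    """Library of lagged state vectors with aligned next-step targets.

    Attributes
    ----------
    E : int
        Embedding dimension (number of lagged coordinates per row).
    tau : int
        Lag between successive coordinates, in time steps.
    library : ndarray, shape (n_rows, E)
        Lagged vectors, most recent coordinate first.
    targets : ndarray, shape (n_rows,)
        ``x_{t+1}`` for the row with time label ``t``.
    source_length : int
        Length of the original series.
    time_labels : ndarray, shape (n_rows,)
        Original time index ``t`` of each row (0-based).
    """

    E: int
    tau: int
    library: np.ndarray
    targets: np.ndarray
    source_length: int
    time_labels: np.ndarray = field(repr=False)

    @property
    def n_rows(self) -> int:
        return self.library.shape[0]


def embed(series, E: int, tau: int = 1) -> DelayEmbedding:
    """Build a delay embedding of a scalar series.

    Every library row has a defined next-step target, so the row count is
    ``len(series) - 1 - (E - 1) * tau``.

    Raises
    ------
    ValueError
        If the series is too short (``insufficient length``) or contains
        non-finite values (``invalid series``).
    """
    x = np.asarray(series, dtype=float).ravel()
    if E < 1 or tau < 1:
        raise ValueError("E and tau must be positive integers")
    if not np.all(np.isfinite(x)):
        raise ValueError("invalid series: non-finite values")
    n = x.size
    n_rows = n - 1 - (E - 1) * tau
    if n_rows < 1:
        raise ValueError(
            f"insufficient length: need at least {(E - 1) * tau + 2} points "
            f"for E={E}, tau={tau}, got {n}"
        )
    t0 = (E - 1) * tau
    labels = np.arange(t0, n - 1)
    # column j holds x_{t - j*tau}
    lib = np.column_stack([x[labels - j * tau] for j in range(E)])
    return DelayEmbedding(
        E=E,
        tau=tau,
        library=lib,
        targets=x[labels + 1],
        source_length=n,
        time_labels=labels,
    )


def _eligible(embedding: DelayEmbedding, exclude) -> np.ndarray:
    mask = np.ones(embedding.n_rows, dtype=bool)
    if exclude:
        mask[np.fromiter(exclude, dtype=int)] = False
    return mask


def knn_search(embedding: DelayEmbedding, query, k: int, exclude=None):
    """k nearest library rows to `query` by Euclidean distance.

    Returns ``(row_ids, distances)`` sorted ascending by
    ``(distance, time label)``; `exclude` is a set of row ids removed from
    the search.
    """
    q = np.asarray(query, dtype=float).ravel()
    if q.size != embedding.E:
        raise ValueError(f"query must have dimension E={embedding.E}")
    mask = _eligible(embedding, exclude)
    n_eligible = int(mask.sum())
    if k < 1 or k > n_eligible:
        raise ValueError(f"not enough neighbours: k={k}, eligible={n_eligible}")
    ids = np.nonzero(mask)[0]
    d = np.sqrt(np.sum((embedding.library[ids] - q) ** 2, axis=1))
    order = np.lexsort((embedding.time_labels[ids], d))[:k]
    return ids[order], d[order]


def _simplex_weights(distances: np.ndarray) -> np.ndarray:
    d_min = distances[0]
    if d_min == 0.0:
        w = (distances == 0.0).astype(float)
    else:
        w = np.exp(-distances / d_min)
    return w / w.sum()


def simplex_forecast(embedding: DelayEmbedding, query, exclude=None) -> float:
    """Forecast the next value of `query` by simplex projection.

    Uses the ``E + 1`` nearest neighbours; the prediction is a convex
    combination of their targets, so it always lies within the neighbours'
    target range.
    """
    k = embedding.E + 1
    mask = _eligible(embedding, exclude)
    if int(mask.sum()) < k:
        raise ValueError(f"library too small: need {k} eligible rows")
    ids, d = knn_search(embedding, query, k, exclude)
    w = _simplex_weights(d)
    assert w.min() >= 0.0 and abs(w.sum() - 1.0) < 1e-9
    return float(w @ embedding.targets[ids])


def simplex_state_update(embedding: DelayEmbedding, state, register=None):
    """Apply the simplex map to a full reservoir state.

    Coordinate 1 of the output is the simplex forecast of `state`; the
    remaining coordinates shift down the lag register.  For ``tau == 1``
    (the default everywhere) this is a plain shift: output coordinates
    ``2..E`` equal input coordinates ``1..E-1``.

    For ``tau > 1`` pass `register`, the ``(E-1)*tau + 1`` most recent
    coordinate-1 values (newest first); the forecast is pushed onto it and
    the new state is the shifted register sampled every `tau` steps.
    Returns ``(new_state, new_register)`` when a register is supplied,
    otherwise just ``new_state``.
    """
    s = np.asarray(state, dtype=float).ravel()
    pred = simplex_forecast(embedding, s)
    if register is not None:
        reg = np.asarray(register, dtype=float).ravel()
        reg = np.concatenate(([pred], reg[:-1]))
        return reg[:: embedding.tau][: embedding.E].copy(), reg
    return np.concatenate(([pred], s[:-1]))


def loo_simplex_skill(series, E: int, tau: int = 1, criterion: str = "rho") -> float:
    """Leave-one-out simplex forecast skill of a series at dimension E.

    Each library row is forecast with its own row excluded; skill is the
    Pearson correlation (``criterion='rho'``) or negative RMSE
    (``criterion='rmse'``) between forecasts and observed targets.
    Implemented over a full pairwise-distance matrix, so it is fast for
    library sizes in the hundreds.
    """
    emb = embed(series, E, tau)
    n = emb.n_rows
    k = E + 1
    if n - 1 < k:
        raise ValueError("insufficient length for leave-one-out forecasting")
    D = cdist(emb.library, emb.library)
    np.fill_diagonal(D, np.inf)
    preds = np.empty(n)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    for i in range(n):
        ids = order[i]
        d = D[i, ids]
        preds[i] = _simplex_weights(d) @ emb.targets[ids]
    if criterion == "rho":
        if np.std(preds) == 0.0 or np.std(emb.targets) == 0.0:
            return 0.0
        return float(pearsonr(preds, emb.targets)[0])
    if criterion == "rmse":
        return -float(np.sqrt(np.mean((preds - emb.targets) ** 2)))
    raise ValueError(f"unknown criterion {criterion!r}")


def select_embedding_dimension(series, E_max: int = 10, tau: int = 1,
                               criterion: str = "rho"):
    """Choose the embedding dimension by leave-one-out forecast skill.

    Evaluates E = 1..E_max and returns ``(E_star, skills)`` where `skills`
    maps each evaluated E to its skill; ties go to the smallest E.
    Deterministic: the same series always yields the same result.
    """
    skills: dict[int, float] = {}
    for E in range(1, E_max + 1):
        try:
            skills[E] = loo_simplex_skill(series, E, tau, criterion)
        except ValueError:
            break
    if not skills:
        raise ValueError("series too short for any embedding dimension")
    best = max(skills, key=lambda E: (skills[E], -E))
    return best, skills
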