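"""Real-time reservoir pipeline: preprocessing, multiplexing, recall, horizon sweep.

A run records a coarse commanded-input sequence (one value per input step)
and fine-grained observations (several per input step) of a living
reservoir.  The processing chain is:

1. :func:`preprocess_counts` — detrend the raw counts into a stationary,
   mean-zero relative residual (the reservoir state signal).
2. :func:`time_multiplex` — fold the fine sequence into one row per input
   step, one column per substep (5 observations per 5-minute input step).
3. :func:`space_multiplex` — concatenate runs under different conditions
   column-wise: three runs of 5 substeps give a 256 × 15 training matrix,
   six runs a 256 × 30 matrix.
4. :func:`recall_task` — train a ridge readout (no intercept; e.g. a 1 × 15
   weight row) to recover the input `lag` steps ago from the state, i.e.
   use the reservoir as a thermometer with memory.
5. :func:`horizon_prediction_task` — sweep prediction horizons and compare
   the reservoir readout's NMSE with a ridge regression on the raw input
   alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .evaluation import correlation_skill, forgetting_curve, nmse
from .readout import readout_predict, train_ridge
from .synthetic import RunRecord

__all__ = [
    "MultiplexedMatrix",
    "preprocess_counts",
    "time_multiplex",
    "space_multiplex",
    "multiplex_run",
    "recall_task",
    "horizon_prediction_task",
]


@dataclass(frozen=True)
class MultiplexedMatrix:
    """Reservoir-state matrix with (condition, replicate, substep) labels."""

    matrix: np.ndarray                  # (T_coarse, C)
    column_labels: tuple                # C tuples (condition, replicate, substep)

    def __post_init__(self):
        if self.matrix.shape[1] != len(self.column_labels):
            raise ValueError("one label per column required")

    @property
    def T(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def preprocess_counts(counts, frac: float = 0.2, eps: float = 1e-9,
                      it: int = 0) -> np.ndarray:
    """Detrend raw counts into a stationary relative residual.

    A slow trend is fitted by locally weighted regression (LOWESS with
    bandwidth fraction `frac`) and the residual is expressed relative to
    the trend: ``(count − trend) / max(trend, eps)``.  The result is
    approximately mean-zero and free of the slow growth/decline of the
    underlying population, leaving the input-driven fluctuations.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if c.size < 20:
        raise ValueError("need at least 20 samples to detrend")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if np.all(c == 0):
        raise ValueError("all-zero counts")
    t = np.arange(c.size, dtype=float)
    trend = sm.nonparametric.lowess(c, t, frac=frac, it=it,
                                    delta=0.01 * c.size, return_sorted=False)
    return (c - trend) / np.maximum(trend, eps)


def time_multiplex(index, substeps: int) -> np.ndarray:
    """Fold a fine sequence into (T_coarse × substeps); row t holds the
    consecutive samples of input interval t, so element (t, s) is fine
    sample ``substeps·t + s``."""
    x = np.asarray(index, dtype=float).ravel()
    if substeps < 1 or x.size % substeps != 0:
        raise ValueError(
            f"fine length {x.size} not divisible by substeps {substeps}")
    return x.reshape(-1, substeps)


def space_multiplex(matrices, labels=None) -> MultiplexedMatrix:
    """Concatenate per-run state matrices column-wise with provenance labels.

    `labels` is one (condition, replicate) pair per run; substep indices
    are appended automatically.
    """
    matrices = [np.atleast_2d(np.asarray(m, dtype=float)) for m in matrices]
    if not matrices:
        raise ValueError("no matrices to multiplex")
    T = matrices[0].shape[0]
    if any(m.shape[0] != T for m in matrices):
        raise ValueError("mismatched row counts across runs")
    if labels is None:
        labels = [("run", i + 1) for i in range(len(matrices))]
    cols = []
    for (cond, rep), m in zip(labels, matrices):
        cols.extend((cond, rep, s) for s in range(m.shape[1]))
    return MultiplexedMatrix(matrix=np.hstack(matrices),
                             column_labels=tuple(cols))


def multiplex_run(record: RunRecord, frac: float = 0.2) -> np.ndarray:
    """Preprocess one run's counts and time-multiplex them."""
    index = preprocess_counts(record.counts, frac=frac)
    return time_multiplex(index, record.substeps_per_input)


def multiplex_records(records, frac: float = 0.2) -> MultiplexedMatrix:
    """Full time- + space-multiplexing of a list of :class:`RunRecord`."""
    mats = [multiplex_run(r, frac=frac) for r in records]
    labels = [(r.condition, r.replicate) for r in records]
    return space_multiplex(mats, labels)


def recall_task(train: MultiplexedMatrix, test: MultiplexedMatrix,
                train_u, test_u, lag: int = 1, lam: float = 0.05,
                washout: int = 0, intercept: bool = False,
                max_lag: int = None):
    """Recover the input `lag` steps ago from the reservoir state.

    Fits W_out (one weight per state column, no intercept by default) on
    the training matrix and scores Pearson r on the test matrix.  When
    `max_lag` is given the full forgetting curve is computed as well.

    Returns a dict with keys ``predictions``, ``observed``, ``r``,
    ``model`` and (optionally) ``curve``.
    """
    utr = np.asarray(train_u, dtype=float).ravel()
    ute = np.asarray(test_u, dtype=float).ravel()
    if train.T != utr.size or test.T != ute.size:
        raise ValueError("state matrices must align with their input sequences")
    model = train_ridge(train.matrix[lag:], utr[: utr.size - lag] if lag else utr,
                        lam=lam, washout=washout, intercept=intercept)
    pred = readout_predict(model, test.matrix[lag:])
    obs = ute[: ute.size - lag] if lag else ute
    out = {
        "predictions": pred,
        "observed": obs,
        "r": correlation_skill(pred, obs),
        "model": model,
    }
    if max_lag is not None:
        out["curve"] = forgetting_curve(train.matrix, test.matrix, utr, ute,
                                        max_lag=max_lag, lam=lam,
                                        washout=washout, intercept=intercept)
    return out


def horizon_prediction_task(states: MultiplexedMatrix, target_signal,
                            horizons, lam: float = 0.05, washout: int = 0,
                            train_frac: float = 0.7, intercept: bool = True,
                            input_signal=None):
    """NMSE versus prediction horizon, reservoir readout against a ridge
    baseline on the raw input.

    For each horizon h a readout is fitted on the first `train_frac` of the
    coarse steps to predict ``y_{t+h}`` from the state at t, and evaluated
    on the rest.  The baseline fits the same ridge regression to the raw
    input value ``u_t`` alone (`input_signal`, defaulting to the target
    itself).  Returns ``{"horizons": ..., "reservoir_nmse": ...,
    "baseline_nmse": ...}``.
    """
    y = np.asarray(target_signal, dtype=float).ravel()
    if states.T != y.size:
        raise ValueError("target must align with coarse steps")
    u = y if input_signal is None else np.asarray(input_signal, dtype=float).ravel()
    if u.size != y.size:
        raise ValueError("input signal must align with the target")
    res_nmse, base_nmse = [], []
    for h in horizons:
        S = states.matrix[: states.T - h] if h else states.matrix
        Su = u[: u.size - h, None] if h else u[:, None]
        yh = y[h:]
        n = yh.size
        split = int(round(train_frac * n))
        m_res = train_ridge(S[:split], yh[:split], lam=lam, washout=washout,
                            intercept=intercept)
        m_base = train_ridge(Su[:split], yh[:split], lam=lam, washout=washout,
                             intercept=intercept)
        res_nmse.append(nmse(readout_predict(m_res, S[split:]), yh[split:]))
        base_nmse.append(nmse(readout_predict(m_base, Su[split:]), yh[split:]))
    return {
        "horizons": np.asarray(list(horizons)),
        "reservoir_nmse": np.asarray(res_nmse),
        "baseline_nmse": np.asarray(base_nmse),
    }
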