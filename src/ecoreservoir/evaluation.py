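"""Reservoir diagnostics: prediction error, echo state property, memory.

* NMSE — squared error normalised by the target variance (0 = perfect,
  1 = mean predictor).
* Correlation skill — Pearson r between predictions and observations.
* Echo state property (ESP) — two reservoir runs from different initial
  states but the same input sequence must converge; the diagnostic is the
  per-step Euclidean distance between the two state trajectories.
* Forgetting curve / memory capacity — how well a trained readout recovers
  the input k steps ago from the current state, as a function of the lag
  k; the summed squared recall correlation over k ≥ 1 is the memory
  capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from .readout import train_ridge, readout_predict
from .reservoirs import StateTrajectory

__all__ = [
    "nmse",
    "correlation_skill",
    "esp_distance",
    "esp_converged",
    "forgetting_curve",
    "ForgettingCurve",
    "EvaluationReport",
]


def nmse(pred, obs) -> float:
    """Σ(pred − obs)² / Σ(obs − mean(obs))²."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size != obs.size or obs.size < 2:
        raise ValueError("pred and obs must have equal length >= 2")
    denom = np.sum((obs - obs.mean()) ** 2)
    if denom == 0.0:
        raise ValueError("zero-variance observations")
    return float(np.sum((pred - obs) ** 2) / denom)


def correlation_skill(pred, obs) -> float:
    """Pearson correlation between predictions and observations."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if np.std(pred) == 0.0 or np.std(obs) == 0.0:
        raise ValueError("zero-variance input to correlation")
    return float(pearsonr(pred, obs)[0])


def esp_distance(run_fn, inputs, init_a, init_b) -> np.ndarray:
    """Per-step distance between two runs under the identical input.

    `run_fn(inputs, init)` must return a :class:`StateTrajectory` (or
    matrix).  Returns d_t = ‖X_t^(a) − X_t^(b)‖₂.  Symmetric in the two
    initial states.
    """
    ta = run_fn(inputs, init_a)
    tb = run_fn(inputs, init_b)
    ma = ta.matrix if isinstance(ta, StateTrajectory) else np.asarray(ta)
    mb = tb.matrix if isinstance(tb, StateTrajectory) else np.asarray(tb)
    return np.linalg.norm(ma - mb, axis=1)


def esp_converged(distances, factor: float = 1e-3, frac: float = 0.1) -> bool:
    """Pass/fail summary of an ESP distance curve.

    Converged when the median of the last `frac` of the curve is below
    `factor` times the median of the first `frac`.
    """
    d = np.asarray(distances, dtype=float).ravel()
    k = max(1, int(round(frac * d.size)))
    head = np.median(d[:k])
    tail = np.median(d[-k:])
    if head == 0.0:
        return tail == 0.0
    return bool(tail < factor * head)


@dataclass(frozen=True)
class ForgettingCurve:
    lags: np.ndarray
    recall_r: np.ndarray            # readout recall of u_{t-k}, per lag
    autocorrelation: np.ndarray     # lag-k autocorrelation baseline of u

    @property
    def memory_capacity(self) -> float:
        """Σ_{k≥1} r(k)², the summed squared recall beyond lag zero."""
        mask = self.lags >= 1
        return float(np.sum(self.recall_r[mask] ** 2))


def forgetting_curve(train_states, test_states, train_input, test_input,
                     max_lag: int = 40, lam: float = 0.05, washout: int = 0,
                     intercept: bool = False) -> ForgettingCurve:
    """Recall of past inputs from reservoir states, per lag.

    For each lag k a readout is trained on the training states to output
    u_{t−k} and scored by Pearson r on the test set.  The baseline is the
    input's own lag-k autocorrelation (what the input "remembers" about
    itself).
    """
    Str = train_states.matrix if isinstance(train_states, StateTrajectory) \
        else np.asarray(train_states, dtype=float)
    Ste = test_states.matrix if isinstance(test_states, StateTrajectory) \
        else np.asarray(test_states, dtype=float)
    utr = np.asarray(train_input, dtype=float).ravel()
    ute = np.asarray(test_input, dtype=float).ravel()
    if Str.shape[0] != utr.size or Ste.shape[0] != ute.size:
        raise ValueError("states and inputs must be aligned")
    if max_lag >= min(utr.size, ute.size) // 4:
        raise ValueError("max_lag must be < T/4")
    lags = np.arange(max_lag + 1)
    recall = np.empty(max_lag + 1)
    autocorr = np.empty(max_lag + 1)
    for k in lags:
        model = train_ridge(Str[k:], utr[: utr.size - k] if k else utr,
                            lam=lam, washout=washout, intercept=intercept)
        pred = readout_predict(model, Ste[k:])
        target = ute[: ute.size - k] if k else ute
        recall[k] = correlation_skill(pred, target)
        autocorr[k] = 1.0 if k == 0 else \
            float(pearsonr(ute[k:], ute[:-k])[0])
    return ForgettingCurve(lags=lags, recall_r=recall, autocorrelation=autocorr)


@dataclass
class EvaluationReport:
    """Bundle of diagnostics for one experiment."""

    nmse_per_horizon: dict = field(default_factory=dict)
    correlation_per_horizon: dict = field(default_factory=dict)
    esp_distances: np.ndarray = None
    esp_converged: bool = None
    forgetting: ForgettingCurve = None
    metadata: dict = field(default_factory=dict)

    @property
    def memory_capacity(self):
        return None if self.forgetting is None else self.forgetting.memory_capacity

    def to_dict(self) -> dict:
        out = {
            "nmse": {str(k): float(v) for k, v in self.nmse_per_horizon.items()},
            "correlation": {str(k): float(v)
                            for k, v in self.correlation_per_horizon.items()},
            "metadata": self.metadata,
        }
        if self.esp_converged is not None:
            out["esp_converged"] = bool(self.esp_converged)
        if self.forgetting is not None:
            out["memory_capacity"] = self.memory_capacity
            out["forgetting_recall_r"] = [float(v) for v in self.forgetting.recall_r]
            out["forgetting_autocorrelation"] = [
                float(v) for v in self.forgetting.autocorrelation]
        return out
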