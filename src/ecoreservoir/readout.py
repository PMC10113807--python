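"""Linear readouts: ridge training, open-loop prediction, closed-loop generation.

Only the readout is trained in reservoir computing.  Given a state
trajectory S (T × feature_dim) and targets y, the readout weights solve the
ridge problem

    W_out = (SᵀS + λI)⁻¹ Sᵀ y

on the rows after an initial washout.  Optionally targets are z-scored with
training-set statistics, stored in the model so predictions are returned on
the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reservoirs import StateTrajectory

__all__ = ["ReadoutModel", "train_ridge", "readout_predict", "closed_loop_generate"]

CLOSED_LOOP_LIMIT = 1e6


@dataclass(frozen=True)
class ReadoutModel:
    """Trained linear readout z_t = W_out · X_t (+ intercept)."""

    w_out: np.ndarray        # (feature_dim [+1], output_dim)
    lam: float
    washout: int
    intercept: bool
    feature_dim: int
    y_mean: np.ndarray = None   # set when targets were standardized
    y_std: np.ndarray = None
    x_mean: np.ndarray = None   # set when features were standardized
    x_std: np.ndarray = None


def _states_matrix(states) -> np.ndarray:
    if isinstance(states, StateTrajectory):
        return states.matrix
    return np.atleast_2d(np.asarray(states, dtype=float))


def train_ridge(states, targets, lam: float = 0.05, washout: int = 50,
                intercept: bool = True, standardize_targets: bool = False,
                standardize_features: bool = False) -> ReadoutModel:
    """Fit readout weights by ridge regression.

    Rows before `washout` are discarded; the design matrix gains a bias
    column when `intercept` is true (the bias weight is penalized like any
    other).  With `standardize_features` the states are z-scored with
    training statistics before the fit, so the penalty acts on a
    scale-invariant design; the statistics are stored in the model and
    re-applied at prediction time.  Raises
    ``LinAlgError('singular; increase lambda')`` when ``λ = 0`` and the
    normal equations are singular.
    """
    S = _states_matrix(states)
    y = np.asarray(targets, dtype=float)
    y2d = y.reshape(-1, 1) if y.ndim == 1 else y
    if S.shape[0] != y2d.shape[0]:
        raise ValueError("states and targets must have equal length")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    S = S[washout:]
    y2d = y2d[washout:]
    feature_dim = S.shape[1]
    y_mean = y_std = x_mean = x_std = None
    if standardize_targets:
        y_mean = y2d.mean(axis=0)
        y_std = y2d.std(axis=0)
        y_std = np.where(y_std == 0, 1.0, y_std)
        y2d = (y2d - y_mean) / y_std
    if standardize_features:
        x_mean = S.mean(axis=0)
        x_std = S.std(axis=0)
        x_std = np.where(x_std == 0, 1.0, x_std)
        S = (S - x_mean) / x_std
    if intercept:
        S = np.column_stack([S, np.ones(S.shape[0])])
    A = S.T @ S + lam * np.eye(S.shape[1])
    if lam == 0.0 and np.linalg.matrix_rank(A) < A.shape[0]:
        raise np.linalg.LinAlgError("singular; increase lambda")
    w = np.linalg.solve(A, S.T @ y2d)
    return ReadoutModel(w_out=w, lam=lam, washout=washout, intercept=intercept,
                        feature_dim=feature_dim, y_mean=y_mean, y_std=y_std,
                        x_mean=x_mean, x_std=x_std)


def readout_predict(model: ReadoutModel, states) -> np.ndarray:
    """Apply the readout to states; inverse-transforms standardized targets.

    Returns a 1-D array for single-output models, else (T, output_dim).
    """
    S = _states_matrix(states)
    if S.shape[1] != model.feature_dim:
        raise ValueError(
            f"feature dimension {S.shape[1]} != model dimension {model.feature_dim}")
    if model.x_mean is not None:
        S = (S - model.x_mean) / model.x_std
    if model.intercept:
        S = np.column_stack([S, np.ones(S.shape[0])])
    z = S @ model.w_out
    if model.y_mean is not None:
        z = z * model.y_std + model.y_mean
    return z[:, 0] if z.shape[1] == 1 else z


def closed_loop_generate(step_fn, model: ReadoutModel, init_state, init_input,
                         n_steps: int, u_bounds=None):
    """Run a reservoir autonomously, feeding the readout back as input.

    The readout must have been trained to predict the next input value from
    the state.  At each step ``u_{t+1} = z_t = model(X_t)`` and
    ``X_{t+1} = step_fn(X_t, u_{t+1})``.  Returns
    ``(generated, trajectory, diverged)``; generation stops early when the
    output magnitude exceeds 1e6.

    `u_bounds` (lo, hi), when given, clamps the fed-back input to that
    range before it re-enters the reservoir — the convention for a
    physical reservoir whose input actuator only operates inside its
    training range.  The recorded output sequence is the raw readout, so
    the generated dynamics are reported unclipped.
    """
    state = np.asarray(init_state, dtype=float).ravel()
    u = np.atleast_1d(np.asarray(init_input, dtype=float))
    generated = []
    states = []
    diverged = False
    for _ in range(n_steps):
        z = readout_predict(model, state.reshape(1, -1))
        u = np.atleast_1d(z[0] if np.ndim(z) else z)
        generated.append(float(u[0]) if u.size == 1 else u.copy())
        if np.max(np.abs(u)) > CLOSED_LOOP_LIMIT:
            diverged = True
            break
        if u_bounds is not None:
            u = np.clip(u, u_bounds[0], u_bounds[1])
        state = np.asarray(step_fn(state, u), dtype=float).ravel()
        if not np.all(np.isfinite(state)) or np.max(np.abs(state)) > CLOSED_LOOP_LIMIT:
            diverged = True
            break
        states.append(state.copy())
    trajectory = StateTrajectory(matrix=np.array(states).reshape(len(states), -1))
    return np.asarray(generated), trajectory, diverged
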