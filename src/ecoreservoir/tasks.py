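"""Benchmark task signals: Lorenz prediction, NARMA emulation, Mackey–Glass,
and uniform random inputs.

Each generator returns a :class:`TaskSignal` holding index-aligned input and
target sequences.  All generators are deterministic given their parameters
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskSignal",
    "gen_lorenz",
    "gen_narma",
    "gen_mackey_glass",
    "gen_uniform_input",
    "NARMA2_FIXED_POINT",
]

# stable root of 0.4 y^2 - 0.6 y + 0.1 = 0: the NARMA2 equilibrium under
# zero input, y* = (0.6 - sqrt(0.2)) / 0.8
NARMA2_FIXED_POINT = (0.6 - np.sqrt(0.2)) / 0.8


@dataclass(frozen=True)
class TaskSignal:
    """Paired input/target sequences with task metadata."""

    u: np.ndarray           # (T,) or (T, input_dim)
    y: np.ndarray           # (T,) or (T, output_dim)
    name: str
    horizon: int = 0
    params: dict = field(default_factory=dict)
    seed: int = None

    def __post_init__(self):
        if len(self.u) != len(self.y):
            raise ValueError("u and y must have equal length after alignment")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite task signal")

    @property
    def T(self) -> int:
        return len(self.u)


def _rk4(f, state, dt):
    k1 = f(state)
    k2 = f(state + 0.5 * dt * k1)
    k3 = f(state + 0.5 * dt * k2)
    k4 = f(state + dt * k3)
    return state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def gen_lorenz(n: int = 3000, dt: float = 0.01, sigma: float = 10.0,
               rho: float = 28.0, beta: float = 8.0 / 3.0,
               init=(1.0, 1.0, 1.0), observe: str = "x", horizon: int = 1,
               subsample: int = 5, discard: int = 1000,
               zscore: bool = True) -> TaskSignal:
    """Lorenz system observed through one component.

    Integrates with fourth-order Runge–Kutta at step `dt`, discards an
    initial transient, keeps every `subsample`-th step, and z-scores the
    observed component.  The target is the same observable `horizon`
    samples ahead; both sequences are trimmed to equal length.
    """
    comp = {"x": 0, "y": 1, "z": 2}[observe]

    def f(s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    n_fine = discard + n * subsample
    state = np.asarray(init, dtype=float)
    obs = np.empty(n_fine)
    for i in range(n_fine):
        state = _rk4(f, state, dt)
        obs[i] = state[comp]
    series = obs[discard::subsample][:n]
    if zscore:
        series = (series - series.mean()) / series.std()
    u = series[: len(series) - horizon] if horizon > 0 else series
    y = series[horizon:]
    return TaskSignal(u=u, y=y, name="lorenz", horizon=horizon,
                      params=dict(dt=dt, sigma=sigma, rho=rho, beta=beta,
                                  subsample=subsample, observe=observe))


def lorenz_trajectory(n: int, dt: float = 0.01, sigma: float = 10.0,
                      rho: float = 28.0, beta: float = 8.0 / 3.0,
                      init=(1.0, 1.0, 1.0)):
    """Raw RK4 Lorenz trajectory (n × 3), no discard/subsampling."""
    def f(s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    state = np.asarray(init, dtype=float)
    out = np.empty((n, 3))
    for i in range(n):
        state = _rk4(f, state, dt)
        out[i] = state
    return out


def gen_narma(order: int, u, alpha: float = 0.3, beta: float = 0.05,
              gamma: float = 1.5, delta: float = 0.1) -> TaskSignal:
    """NARMA nonlinear autoregression driven by an input sequence in [0, 0.5].

    NARMA2:
        y_{t+1} = 0.4 y_t + 0.4 y_t y_{t-1} + 0.6 u_t^3 + 0.1
    Orders n in {3, 4, 5, 10}:
        y_{t+1} = α y_t + β y_t Σ_{i=0}^{n-1} y_{t-i} + γ u_{t-n+1} u_t + δ

    History is initialised to zero.  Raises on divergence (|y| > 1e3),
    which signals the input needs rescaling.
    """
    if order not in (2, 3, 4, 5, 10):
        raise ValueError(f"unsupported NARMA order {order}")
    u = np.asarray(u, dtype=float).ravel()
    if u.min() < 0.0 or u.max() > 0.5:
        raise ValueError("NARMA input must lie in [0, 0.5]")
    T = u.size
    y = np.zeros(T)
    for t in range(T - 1):
        if order == 2:
            y_prev = y[t - 1] if t >= 1 else 0.0
            y[t + 1] = 0.4 * y[t] + 0.4 * y[t] * y_prev + 0.6 * u[t] ** 3 + 0.1
        else:
            acc = y[max(0, t - order + 1): t + 1].sum()
            u_lag = u[t - order + 1] if t >= order - 1 else 0.0
            y[t + 1] = alpha * y[t] + beta * y[t] * acc + gamma * u_lag * u[t] + delta
        if abs(y[t + 1]) > 1e3:
            raise FloatingPointError("unstable NARMA; rescale input")
    return TaskSignal(u=u, y=y, name=f"narma{order}", horizon=0,
                      params=dict(order=order, alpha=alpha, beta=beta,
                                  gamma=gamma, delta=delta))


def gen_mackey_glass(n: int = 3000, dt: float = 0.1, tau_delay: float = 17.0,
                     beta_mg: float = 0.2, gamma_mg: float = 0.1,
                     exponent: float = 10.0, history: float = 1.2,
                     sample_step: float = 1.0) -> TaskSignal:
    """Mackey–Glass delay differential equation, sampled every `sample_step`.

        dx/dt = β x(t−τ) / (1 + x(t−τ)^n) − γ x(t)

    Integrated with RK4 on an internal grid of step `dt`; the delayed value
    is obtained by linear interpolation on the stored fine grid.  `history`
    sets the constant value of x on [−τ, 0].  With defaults (τ=17) the
    dynamics are chaotic; τ=2 converges toward the equilibrium
    x* = (β/γ − 1)^{1/n}.
    """
    if tau_delay <= 0:
        raise ValueError("tau_delay must be positive")
    stride = int(round(sample_step / dt))
    n_fine = n * stride
    delay_steps = tau_delay / dt
    hist_len = int(np.ceil(delay_steps)) + 2
    buf = np.full(hist_len + n_fine, float(history))

    def delayed(i_now, offset):
        # value at time (i_now + offset)*dt - tau, linear interpolation
        pos = hist_len + i_now + offset - delay_steps
        i0 = int(np.floor(pos))
        frac = pos - i0
        return buf[i0] * (1 - frac) + buf[min(i0 + 1, hist_len + i_now)] * frac

    for i in range(n_fine):
        x = buf[hist_len + i - 1] if i > 0 else float(history)

        def f_at(offset, xv):
            xd = delayed(i - 1, offset)
            return beta_mg * xd / (1.0 + xd ** exponent) - gamma_mg * xv

        k1 = f_at(0.0, x)
        k2 = f_at(0.5, x + 0.5 * dt * k1)
        k3 = f_at(0.5, x + 0.5 * dt * k2)
        k4 = f_at(1.0, x + dt * k3)
        buf[hist_len + i] = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    series = buf[hist_len - 1 + stride::stride][:n]
    u = series[:-1]
    y = series[1:]
    return TaskSignal(u=u, y=y, name="mackey_glass", horizon=1,
                      params=dict(dt=dt, tau_delay=tau_delay, beta_mg=beta_mg,
                                  gamma_mg=gamma_mg, exponent=exponent,
                                  sample_step=sample_step))


def gen_uniform_input(n: int, lo: float = 0.0, hi: float = 0.5,
                      seed: int = 0) -> TaskSignal:
    """i.i.d. Uniform[lo, hi) input; the target mirrors the input."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    rng = np.random.default_rng(seed)
    u = rng.uniform(lo, hi, size=n)
    return TaskSignal(u=u, y=u.copy(), name="uniform", horizon=0,
                      params=dict(lo=lo, hi=hi), seed=seed)
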