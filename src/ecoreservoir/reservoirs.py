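"""Reservoir dynamics.

Three reservoir families share the same interface (step + run returning a
:class:`StateTrajectory`):

* :class:`EcoReservoir` — the simplex-projection reservoir.  The state
  evolves as ``X_{t+1} = f(W_in u_t + f_simp(X_t))`` with ``f`` the
  identity, where ``f_simp`` forecasts the reconstructed ecological
  dynamics one step ahead ("project then add"); the alternative order
  ``X_{t+1} = f_simp(X_t + W_in u_t)`` ("add then project") is available
  as a variant flag.
* Lotka–Volterra toy reservoir — two coupled difference equations used as
  a reservoir of size 2: ``X_{t+1} = W_in u_t + g(X_t)`` with ``g`` the
  two-species map.
* :class:`EsnReservoir` — the classic echo state network baseline,
  ``X_{t+1} = tanh(W_in u_t + W X_t)`` with untrained random recurrent
  weights rescaled to a prescribed spectral radius.

Species multiplexing concatenates the state trajectories of reservoirs
built from different species' time series into one wide state matrix; the
total reservoir size is the sum of the individual embedding dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .embedding import DelayEmbedding, simplex_forecast

__all__ = [
    "InputWeights",
    "EcoReservoir",
    "LvParams",
    "EsnReservoir",
    "StateTrajectory",
    "make_input_weights",
    "erc_step",
    "erc_run",
    "multiplex_states",
    "lv_map_step",
    "lv_reservoir_run",
    "esn_init",
    "esn_run",
]

DIVERGENCE_LIMIT = 1e6

# input scaling 0.3 throughout: uniform random weights on [-1, 1] are
# multiplied by 0.3 to moderate the influence of the input on the state
DEFAULT_INPUT_SCALE = 0.3


@dataclass(frozen=True)
class InputWeights:
    """Input-to-reservoir weight matrix W_in.

    Entries are i.i.d. Uniform[-scale, scale]; a `sparsity` fraction of
    them (exactly ``round(sparsity * size)`` entries) is forced to zero.
    """

    matrix: np.ndarray  # (state_dim, input_dim)
    scale: float
    sparsity: float
    seed: int

    @property
    def state_dim(self) -> int:
        return self.matrix.shape[0]

    @property
    def input_dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class EcoReservoir:
    """Per-species simplex-projection reservoir.

    The embedding library is the reconstructed attractor of one species'
    time series; the E-dimensional state is a point in that state space,
    perturbed by inputs and propagated by simplex projection.
    """

    embedding: DelayEmbedding
    w_in: InputWeights
    state: np.ndarray = None
    variant: str = "project_then_add"
    _register: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.w_in.state_dim != self.embedding.E:
            raise ValueError("w_in state_dim must equal embedding dimension E")
        if self.variant not in ("project_then_add", "add_then_project"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.state is None:
            # start from the last embedded vector of the library
            self.state = self.embedding.library[-1].copy()
        self.state = np.asarray(self.state, dtype=float).ravel()
        if self.state.size != self.embedding.E:
            raise ValueError("state dimension must equal E")
        if self.embedding.tau > 1 and self._register is None:
            reg_len = (self.embedding.E - 1) * self.embedding.tau + 1
            self._register = np.zeros(reg_len)
            self._register[:: self.embedding.tau] = self.state


@dataclass(frozen=True)
class LvParams:
    """Two-species Lotka–Volterra map parameters.

    ``r_x, r_y`` are growth rates (shared between the linear and
    density-dependent terms); ``beta_xy`` is the influence of species y on
    x and ``beta_yx`` of x on y.  Defaults are the grid-searched values
    used for the toy reservoir demonstration.
    """

    r_x: float = 3.0
    r_y: float = 2.7
    beta_xy: float = -0.2
    beta_yx: float = 0.2


@dataclass
class EsnReservoir:
    N: int
    W: np.ndarray
    w_in: InputWeights
    activation: str
    spectral_radius: float
    density: float
    seed: int
    state: np.ndarray


@dataclass(frozen=True)
class StateTrajectory:
    """Reservoir states over time; row t is the state after input t."""

    matrix: np.ndarray  # (T, state_dim)
    washout: int = 0

    @property
    def T(self) -> int:
        return self.matrix.shape[0]

    @property
    def state_dim(self) -> int:
        return self.matrix.shape[1]


def make_input_weights(state_dim: int, input_dim: int = 1,
                       scale: float = DEFAULT_INPUT_SCALE,
                       sparsity: float = 0.0, seed: int = 0) -> InputWeights:
    """Draw W_in ~ Uniform[-1,1]·scale with a given fraction of zeros."""
    if not 0.0 <= sparsity <= 1.0:
        raise ValueError("sparsity must lie in [0, 1]")
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    m = rng.uniform(-1.0, 1.0, size=(state_dim, input_dim)) * scale
    n_zero = round(sparsity * m.size)
    if n_zero:
        idx = rng.choice(m.size, size=n_zero, replace=False)
        m.flat[idx] = 0.0
    return InputWeights(matrix=m, scale=scale, sparsity=sparsity, seed=seed)


def _as_input(u, input_dim: int) -> np.ndarray:
    v = np.atleast_1d(np.asarray(u, dtype=float)).ravel()
    if v.size != input_dim:
        raise ValueError(f"input dimension {v.size} != expected {input_dim}")
    return v


def _as_input_matrix(inputs, input_dim: int) -> np.ndarray:
    """Normalise inputs to shape (T, input_dim); 1-D sequences become columns."""
    arr = np.asarray(inputs, dtype=float)
    if arr.ndim <= 1:
        arr = arr.reshape(-1, 1)
    if arr.shape[1] != input_dim:
        raise ValueError(f"input dimension {arr.shape[1]} != expected {input_dim}")
    return arr


def erc_step(reservoir: EcoReservoir, u) -> np.ndarray:
    """Advance the simplex reservoir one step; mutates and returns state."""
    emb = reservoir.embedding
    iw = reservoir.w_in.matrix @ _as_input(u, reservoir.w_in.input_dim)
    tau = emb.tau
    if reservoir.variant == "add_then_project":
        if tau == 1:
            base = reservoir.state + iw
            pred = simplex_forecast(emb, base)
            new = np.concatenate(([pred], base[:-1]))
            reservoir.state = new
        else:
            reg = reservoir._register.copy()
            reg[::tau] += iw
            base = reg[::tau][: emb.E]
            pred = simplex_forecast(emb, base)
            reg = np.concatenate(([pred], reg[:-1]))
            reservoir._register = reg
            reservoir.state = reg[::tau][: emb.E].copy()
    else:  # project_then_add
        if tau == 1:
            pred = simplex_forecast(emb, reservoir.state)
            reservoir.state = np.concatenate(([pred], reservoir.state[:-1])) + iw
        else:
            pred = simplex_forecast(emb, reservoir.state)
            reg = np.concatenate(([pred], reservoir._register[:-1]))
            reg[::tau] += iw
            reservoir._register = reg
            reservoir.state = reg[::tau][: emb.E].copy()
    return reservoir.state


def erc_run(reservoir: EcoReservoir, inputs, init_state=None) -> StateTrajectory:
    """Drive the simplex reservoir with an input sequence.

    Row t of the trajectory is the state after consuming input t.
    Deterministic given the inputs and the initial state.
    """
    inputs = _as_input_matrix(inputs, reservoir.w_in.input_dim)
    if init_state is not None:
        reservoir.state = np.asarray(init_state, dtype=float).ravel()
        if reservoir.embedding.tau > 1:
            reg = np.zeros((reservoir.embedding.E - 1) * reservoir.embedding.tau + 1)
            reg[:: reservoir.embedding.tau] = reservoir.state
            reservoir._register = reg
    T = inputs.shape[0]
    out = np.empty((T, reservoir.embedding.E))
    for t in range(T):
        s = erc_step(reservoir, inputs[t])
        if not np.all(np.isfinite(s)) or np.max(np.abs(s)) > DIVERGENCE_LIMIT:
            raise FloatingPointError(f"diverged at step {t}")
        out[t] = s
    return StateTrajectory(matrix=out)


def multiplex_states(trajectories) -> StateTrajectory:
    """Concatenate per-species trajectories column-wise.

    The combined state dimension ("total reservoir size") is the sum of the
    individual state dimensions; column j of species s sits at offset
    ``sum_{i<s} dim_i + j``.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("no trajectories to multiplex")
    T = trajectories[0].T
    if any(tr.T != T for tr in trajectories):
        raise ValueError("mismatched trajectory lengths")
    washout = max(tr.washout for tr in trajectories)
    return StateTrajectory(
        matrix=np.hstack([tr.matrix for tr in trajectories]), washout=washout
    )


def lv_map_step(state, params: LvParams):
    """One iterate of the two-species Lotka–Volterra difference map.

    x' = x (r_x − r_x x + β_xy y),  y' = y (r_y − r_y y + β_yx x).
    Zero is absorbing for each species (extinction).
    """
    x, y = float(state[0]), float(state[1])
    return np.array([
        x * (params.r_x - params.r_x * x + params.beta_xy * y),
        y * (params.r_y - params.r_y * y + params.beta_yx * x),
    ])


def lv_reservoir_run(params: LvParams, w_in: InputWeights, inputs,
                     init=(0.5, 0.5)) -> StateTrajectory:
    """Use the LV map as a reservoir of size 2: X_{t+1} = W_in u_t + g(X_t)."""
    if w_in.state_dim != 2:
        raise ValueError("LV reservoir requires state_dim = 2 input weights")
    inputs = _as_input_matrix(inputs, w_in.input_dim)
    state = np.asarray(init, dtype=float).ravel()
    if state.size != 2:
        raise ValueError("init must be a 2-vector")
    T = inputs.shape[0]
    out = np.empty((T, 2))
    for t in range(T):
        state = w_in.matrix @ _as_input(inputs[t], w_in.input_dim) \
            + lv_map_step(state, params)
        if not np.all(np.isfinite(state)) or np.max(np.abs(state)) > DIVERGENCE_LIMIT:
            raise FloatingPointError(f"diverged at step {t}")
        out[t] = state
    return StateTrajectory(matrix=out)


def esn_init(N: int, input_dim: int = 1, spectral_radius: float = 0.95,
             density: float = 0.1, input_scale: float = DEFAULT_INPUT_SCALE,
             seed: int = 0, activation: str = "tanh") -> EsnReservoir:
    """Random recurrent reservoir rescaled to a prescribed spectral radius."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    if spectral_radius <= 0:
        raise ValueError("spectral_radius must be positive")
    cur = seed
    while True:
        rng = np.random.default_rng(cur)
        W = rng.uniform(-1.0, 1.0, size=(N, N))
        W *= rng.random(size=(N, N)) < density
        radius = np.max(np.abs(np.linalg.eigvals(W)))
        if radius > 0:
            break
        warnings.warn(f"all-zero/nilpotent W at seed {cur}; redrawing with seed {cur + 1}")
        cur += 1
    W *= spectral_radius / radius
    w_in = make_input_weights(N, input_dim, scale=input_scale, sparsity=0.0,
                              seed=cur)
    return EsnReservoir(N=N, W=W, w_in=w_in, activation=activation,
                        spectral_radius=spectral_radius, density=density,
                        seed=seed, state=np.zeros(N))


def esn_run(reservoir: EsnReservoir, inputs, init=None) -> StateTrajectory:
    """Run the ESN: X_{t+1} = f(W_in u_t + W X_t), f = tanh or identity."""
    inputs = _as_input_matrix(inputs, reservoir.w_in.input_dim)
    f = np.tanh if reservoir.activation == "tanh" else (lambda z: z)
    state = (np.zeros(reservoir.N) if init is None
             else np.asarray(init, dtype=float).ravel())
    if state.size != reservoir.N:
        raise ValueError("init must be an N-vector")
    T = inputs.shape[0]
    out = np.empty((T, reservoir.N))
    for t in range(T):
        state = f(reservoir.w_in.matrix @ _as_input(inputs[t], reservoir.w_in.input_dim)
                  + reservoir.W @ state)
        out[t] = state
    reservoir.state = state
    return StateTrajectory(matrix=out)
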