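"""Synthetic ecological time series.

Two generators stand in for the empirical data streams a reservoir-computing
study of ecological dynamics consumes:

* :func:`simulate_community` — an S-species discrete-time community
  (generalised Lotka–Volterra / Ricker-type map with additive process
  noise), the analogue of multi-species field time series such as
  fish-catch records or DNA-quantified prokaryote communities.  Each
  species' series can seed its own delay-embedding reservoir.

* :func:`simulate_driven_population` — a single population whose growth
  responds to a temperature input that changes at coarse 5-substep
  intervals while the population is observed every substep.  This is a
  documented surrogate for a laboratory microbial population driven by a
  programmable temperature regulator; the true response function of such
  an organism is unknown, so the surrogate only reproduces the structural
  features that matter for reservoir computing: temperature inertia,
  nonlinear density dependence, contraction toward a temperature-dependent
  carrying capacity (the source of common-signal synchronization), and
  nutrient-condition presets with distinguishable dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CommunityParams",
    "DrivenPopulationParams",
    "RunRecord",
    "random_community_params",
    "simulate_community",
    "simulate_driven_population",
    "NUTRIENT_PRESETS",
]


@dataclass(frozen=True)
class CommunityParams:
    """Parameters of an S-species stochastic community map.

    x_{i,t+1} = max(0, x_{i,t} (r_i − r_i x_{i,t} + Σ_{j≠i} B_ij x_{j,t}) + ε_{i,t})

    with ε ~ Normal(0, process_noise_sd).  The diagonal of B is zero
    (self-limitation is the −r_i x_i term).
    """

    S: int
    r: np.ndarray                  # (S,) growth rates
    B: np.ndarray                  # (S, S) interaction matrix, zero diagonal
    process_noise_sd: float = 0.01
    obs_noise_sd: float = 0.0
    burn_in: int = 200
    seed: int = 0

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        B = np.asarray(self.B, dtype=float)
        if self.S < 1 or r.shape != (self.S,) or B.shape != (self.S, self.S):
            raise ValueError("inconsistent community parameter shapes")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(B))):
            raise ValueError("non-finite community parameters")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "B", B * (1 - np.eye(self.S)))


def random_community_params(S: int, seed: int = 0,
                            r_range=(2.7, 3.3),
                            interaction_strength: float = 0.25,
                            connectance: float = 0.3,
                            process_noise_sd: float = 0.01,
                            obs_noise_sd: float = 0.0,
                            burn_in: int = 200) -> CommunityParams:
    """Draw a random community in the fluctuating (chaotic) regime.

    Growth rates are uniform on `r_range` — the range where the underlying
    single-species map fluctuates chaotically rather than settling on a
    fixed point — and off-diagonal interactions are ±Uniform(0,
    interaction_strength) present with probability `connectance`.
    """
    rng = np.random.default_rng(seed)
    r = rng.uniform(*r_range, size=S)
    B = rng.uniform(-interaction_strength, interaction_strength, size=(S, S))
    B *= rng.random(size=(S, S)) < connectance
    np.fill_diagonal(B, 0.0)
    return CommunityParams(S=S, r=r, B=B, process_noise_sd=process_noise_sd,
                           obs_noise_sd=obs_noise_sd, burn_in=burn_in, seed=seed)


def simulate_community(params: CommunityParams, n: int, init=None):
    """Simulate n post-burn-in steps of the community.

    Returns an (n, S) array of abundances (non-negative by construction;
    observation noise, if any, is added after the dynamics and clipped at
    zero).  A warning is emitted if every species goes extinct.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(params.seed)
    S = params.S
    x = (np.full(S, 0.5) if init is None
         else np.asarray(init, dtype=float).ravel().copy())
    total = params.burn_in + n
    out = np.empty((total, S))
    eps = rng.normal(0.0, params.process_noise_sd, size=(total, S)) \
        if params.process_noise_sd > 0 else np.zeros((total, S))
    for t in range(total):
        growth = params.r - params.r * x + params.B @ x
        x = np.maximum(0.0, x * growth + eps[t])
        out[t] = x
    series = out[params.burn_in:]
    if np.all(series[-1] <= 1e-12):
        warnings.warn("all-extinct community", stacklevel=2)
    if params.obs_noise_sd > 0:
        series = np.maximum(
            0.0, series + rng.normal(0.0, params.obs_noise_sd, size=series.shape))
    return series


# ---------------------------------------------------------------------------
# temperature-driven single population


def _piecewise_peak(T, T_lo, T_peak, T_hi, v_lo, v_peak, v_hi):
    """Piecewise-linear peaked response over temperature."""
    T = np.asarray(T, dtype=float)
    up = v_lo + (v_peak - v_lo) * (T - T_lo) / (T_peak - T_lo)
    down = v_peak + (v_hi - v_peak) * (T - T_peak) / (T_hi - T_peak)
    return np.clip(np.where(T <= T_peak, up, down),
                   min(v_lo, v_hi, v_peak), v_peak)


@dataclass(frozen=True)
class DrivenPopulationParams:
    """Surrogate temperature-driven population.

    The population follows a Ricker-logistic map per fine substep,

        p_{s+1} = p_s · exp(r(T̃_s) (1 − p_s / K(T̃_s))),

    where the effective temperature T̃ relaxes toward the commanded input
    with first-order inertia `thermal_lag` (fraction of the gap closed per
    substep — the medium takes time to reach the set temperature).  r(T)
    and K(T) are piecewise-linear and peaked at `T_peak`; `k_scale` and
    `r_scale` differ between nutrient presets.  Observations are
    Poisson-like noisy counts: count = p + obs_noise_sd·√p·N(0,1), clipped
    at zero (exact when obs_noise_sd = 0).
    """

    k_scale: float = 200.0          # cells per frame at the thermal optimum
    r_scale: float = 0.6            # per-substep growth rate at the optimum
    T_lo: float = 8.0
    T_peak: float = 25.0
    T_hi: float = 36.0
    thermal_lag: float = 0.5
    substeps_per_input: int = 5
    obs_noise_sd: float = 0.0
    seed: int = 0

    def K(self, T):
        return _piecewise_peak(T, self.T_lo, self.T_peak, self.T_hi,
                               0.25 * self.k_scale, self.k_scale,
                               0.35 * self.k_scale)

    def r(self, T):
        return _piecewise_peak(T, self.T_lo, self.T_peak, self.T_hi,
                               0.15 * self.r_scale, self.r_scale,
                               0.25 * self.r_scale)


# stand-ins for three medium concentrations: richer medium supports a larger
# carrying capacity, faster growth, a higher thermal optimum and faster
# thermal equilibration, so the three conditions act as reservoirs with
# different hyperparameters and respond distinguishably to the same input
NUTRIENT_PRESETS = {
    "low": DrivenPopulationParams(k_scale=120.0, r_scale=0.15, T_peak=20.0,
                                  thermal_lag=0.25),
    "med": DrivenPopulationParams(k_scale=200.0, r_scale=0.45, T_peak=25.0,
                                  thermal_lag=0.5),
    "high": DrivenPopulationParams(k_scale=320.0, r_scale=0.9, T_peak=30.0,
                                   thermal_lag=0.85),
}


@dataclass(frozen=True)
class RunRecord:
    """One real-time run: coarse inputs plus fine-grained observations."""

    condition: str
    replicate: int
    input_temps: np.ndarray        # (T_coarse,) commanded temperature, °C
    sensor_temps: np.ndarray       # (T_coarse * substeps,) effective temp, °C
    counts: np.ndarray             # same length as sensor_temps
    substeps_per_input: int

    def __post_init__(self):
        fine = len(self.input_temps) * self.substeps_per_input
        if len(self.sensor_temps) != fine or len(self.counts) != fine:
            raise ValueError(
                "fine sequences must have substeps_per_input × coarse length")

    @property
    def n_inputs(self) -> int:
        return len(self.input_temps)

    @property
    def n_fine(self) -> int:
        return len(self.counts)


def simulate_driven_population(input_temps,
                               params: DrivenPopulationParams = None,
                               condition: str = "med", replicate: int = 1,
                               init_p: float = None,
                               init_T: float = None) -> RunRecord:
    """Simulate a temperature-driven population run.

    `input_temps` is the coarse commanded-temperature sequence (one value
    per input step, typically 256); the record contains
    ``substeps_per_input`` observations per input step (1280 for 256 at the
    default 5).  Zero observation noise returns the exact population.
    """
    if params is None:
        params = NUTRIENT_PRESETS[condition]
    u = np.asarray(input_temps, dtype=float).ravel()
    if u.size < 1:
        raise ValueError("need at least one input step")
    if np.any(params.K(u) <= 0):
        raise ValueError("non-positive carrying capacity over the input range")
    rng = np.random.default_rng(params.seed)
    sub = params.substeps_per_input
    n_fine = u.size * sub
    p = 0.5 * params.k_scale if init_p is None else float(init_p)
    T_eff = float(u[0]) if init_T is None else float(init_T)
    sensor = np.empty(n_fine)
    pops = np.empty(n_fine)
    for s in range(n_fine):
        target = u[s // sub]
        T_eff += params.thermal_lag * (target - T_eff)
        p = p * np.exp(params.r(T_eff) * (1.0 - p / params.K(T_eff)))
        sensor[s] = T_eff
        pops[s] = p
    if params.obs_noise_sd > 0:
        counts = np.maximum(
            0.0, pops + params.obs_noise_sd * np.sqrt(pops)
            * rng.standard_normal(n_fine))
    else:
        counts = pops.copy()
    return RunRecord(condition=condition, replicate=replicate, input_temps=u,
                     sensor_temps=sensor, counts=counts,
                     substeps_per_input=sub)
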