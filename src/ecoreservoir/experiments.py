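"""Standard experiment protocols.

Each function runs one complete, seeded experiment of the benchmark
battery — building reservoirs from synthetic ecological time series,
driving them with a task signal, training a ridge readout, and scoring the
result.  These are the protocols the example scripts and the acceptance
battery execute; all sizes and signal conditions are fixed here so every
entry point reproduces the same study design.

Chosen conditions (see docs/methods.md for rationale):

* Lorenz prediction: 1000 samples at 0.2 time-unit spacing (RK4 dt=0.01,
  every 20th step), z-scored observable, horizon 1.
* Community libraries: 400 steps for task experiments, 200 for ESP runs.
* Readout: ridge λ=0.05, washout 50, intercept, features and targets
  standardized with training statistics.
* ESP forcing: uniform input on [0, 3] — strong enough for the common
  input to dominate the reservoirs' intrinsic dynamics.
* Real-time runs: 256 coarse steps of uniform temperature on [12, 24] °C
  (below the surrogate's thermal optima, so the population's response is
  monotone in temperature).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .embedding import embed, select_embedding_dimension
from .evaluation import correlation_skill, forgetting_curve, nmse
from .readout import closed_loop_generate, readout_predict, train_ridge
from .reservoirs import (EcoReservoir, erc_run, erc_step, esn_init, esn_run,
                         lv_reservoir_run, make_input_weights,
                         multiplex_states, LvParams)
from .synthetic import (NUTRIENT_PRESETS, random_community_params,
                        simulate_community, simulate_driven_population)
from .realtime import multiplex_records, recall_task
from .tasks import gen_lorenz, gen_mackey_glass, gen_narma, gen_uniform_input

__all__ = [
    "build_reservoirs",
    "fit_and_score",
    "lorenz_task",
    "multiplex_sweep",
    "lv_vs_baseline",
    "narma_emulation",
    "esp_suite",
    "closed_loop_suite",
    "memory_suite",
    "realtime_recall_suite",
]

RIDGE_KW = dict(lam=0.05, washout=50, intercept=True,
                standardize_targets=True, standardize_features=True)


def build_reservoirs(series, seed: int, E_max: int = 8, E_min: int = 2,
                     input_scale: float = 0.3,
                     variant: str = "project_then_add"):
    """One simplex reservoir per species column; E chosen by forecast skill.

    The embedding dimension is floored at `E_min` (a reservoir needs at
    least one lag of memory); constant/extinct series are skipped.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    out = []
    for i in range(series.shape[1]):
        x = series[:, i]
        if np.std(x) < 1e-12:
            continue
        E, _ = select_embedding_dimension(x, E_max=E_max)
        E = max(E, E_min)
        emb = embed(x, E)
        w_in = make_input_weights(E, 1, scale=input_scale,
                                  seed=(seed * 100003 + 7919 * i) % (2**31))
        out.append(EcoReservoir(embedding=emb, w_in=w_in, variant=variant))
    return out


def fit_and_score(states, targets, train_frac: float = 0.7, **ridge_kw):
    """Temporal-split ridge fit; returns (correlation, nmse) on the test part."""
    kw = {**RIDGE_KW, **ridge_kw}
    S = states.matrix if hasattr(states, "matrix") else np.asarray(states)
    y = np.asarray(targets, dtype=float).ravel()
    split = int(round(train_frac * len(y)))
    model = train_ridge(S[:split], y[:split], **kw)
    pred = readout_predict(model, S[split:])
    return correlation_skill(pred, y[split:]), nmse(pred, y[split:])


def lorenz_task(n: int = 1000, subsample: int = 20, horizon: int = 1):
    return gen_lorenz(n=n, dt=0.01, subsample=subsample, horizon=horizon)


def multiplex_sweep(n_species_list=(1, 10, 50), n_seeds: int = 10,
                    seed: int = 0, lib_len: int = 400, task=None):
    """Lorenz one-step prediction correlation versus community diversity.

    For each community size, `n_seeds` random communities are drawn, each
    species seeds its own reservoir, states are species-multiplexed, and
    the readout's test correlation is recorded.  Returns
    ``{n_species: [corr per seed]}``.
    """
    sig = task or lorenz_task()
    results = {}
    for n_sp in n_species_list:
        corrs = []
        for rep in range(n_seeds):
            s = (seed * 10007 + rep) % (2**31)
            comm = simulate_community(random_community_params(n_sp, seed=s),
                                      lib_len)
            rs = build_reservoirs(comm, seed=s)
            states = multiplex_states([erc_run(r, sig.u) for r in rs])
            corrs.append(fit_and_score(states, sig.y)[0])
        results[n_sp] = corrs
    return results


def lv_vs_baseline(n_seeds: int = 10, seed: int = 0, amplitude: float = 0.3):
    """Lotka–Volterra toy reservoir against ridge regression on the raw input.

    The Lorenz observable is min-max centered to [−amplitude, +amplitude]
    so the two-species reservoir stays inside its contracting basin.
    Returns a list of (reservoir_nmse, baseline_nmse) pairs, one per
    input-weight draw; divergent draws are recorded as (inf, baseline).
    """
    lo = gen_lorenz(n=1000, dt=0.01, subsample=5, horizon=1, zscore=False)
    lo_min, lo_rng = lo.u.min(), lo.u.max() - lo.u.min()
    u = ((lo.u - lo_min) / lo_rng - 0.5) * 2 * amplitude
    y = ((lo.y - lo_min) / lo_rng - 0.5) * 2 * amplitude
    split = int(round(0.7 * len(u)))
    base_model = train_ridge(u[:split, None], y[:split], **RIDGE_KW)
    base = nmse(readout_predict(base_model, u[split:, None]), y[split:])
    pairs = []
    for rep in range(n_seeds):
        w = make_input_weights(2, 1, scale=0.3,
                               seed=(seed * 7919 + rep) % (2**31))
        try:
            st = lv_reservoir_run(LvParams(), w, u)
        except FloatingPointError:
            pairs.append((float("inf"), base))
            continue
        model = train_ridge(st.matrix[:split], y[:split], **RIDGE_KW)
        pairs.append((nmse(readout_predict(model, st.matrix[split:]),
                           y[split:]), base))
    return pairs


def narma_emulation(order: int = 2, n_species: int = 20, seed: int = 0,
                    n: int = 1000, lib_len: int = 400):
    """Species-multiplexed NARMA emulation against the input-only baseline.

    Returns ``(reservoir_nmse, baseline_nmse)`` on the held-out 30%.
    """
    u = gen_uniform_input(n, 0.0, 0.5, seed=(seed * 31 + 5) % (2**31)).u
    sig = gen_narma(order, u)
    comm = simulate_community(
        random_community_params(n_species, seed=seed), lib_len)
    rs = build_reservoirs(comm, seed=seed)
    states = multiplex_states([erc_run(r, sig.u) for r in rs])
    _, res = fit_and_score(states, sig.y)
    split = int(round(0.7 * sig.T))
    base_model = train_ridge(sig.u[:split, None], sig.y[:split], **RIDGE_KW)
    base = nmse(readout_predict(base_model, sig.u[split:, None]), sig.y[split:])
    return res, base


def esp_suite(n_species: int = 10, seed: int = 0, lib_len: int = 200,
              T: int = 200, amplitude: float = 3.0):
    """Echo-state-property battery over one community's reservoirs.

    For each species: two runs from random on-attractor initial states
    under the same uniform input (convergence test) and a third run under
    a different input sequence (control).  Returns a list of dicts with
    ``converged`` (distance < 1e−3 of its initial value within 100 steps)
    and ``control_ratio`` (final / initial distance across inputs).
    """
    comm = simulate_community(random_community_params(n_species, seed=seed),
                              lib_len)
    u_same = gen_uniform_input(T, 0.0, amplitude, seed=(seed * 3 + 11) % (2**31)).u
    u_diff = gen_uniform_input(T, 0.0, amplitude, seed=(seed * 3 + 12) % (2**31)).u
    rng = np.random.default_rng((seed * 3 + 7) % (2**31))
    rs = build_reservoirs(comm, seed=seed)
    out = []
    for r in rs[:n_species]:
        emb, w = r.embedding, r.w_in
        ia = emb.library[rng.integers(emb.n_rows)]
        ib = emb.library[rng.integers(emb.n_rows)]
        ta = erc_run(EcoReservoir(embedding=emb, w_in=w), u_same, init_state=ia)
        tb = erc_run(EcoReservoir(embedding=emb, w_in=w), u_same, init_state=ib)
        d = np.linalg.norm(ta.matrix - tb.matrix, axis=1)
        converged = bool(d[0] == 0 or np.min(d[:100]) < 1e-3 * d[0])
        tc = erc_run(EcoReservoir(embedding=emb, w_in=w), u_diff, init_state=ib)
        dc = np.linalg.norm(ta.matrix - tc.matrix, axis=1)
        out.append({
            "converged": converged,
            "distance_curve": d,
            "control_ratio": float(dc[-1] / dc[0]) if dc[0] > 0 else np.inf,
        })
    return out


def closed_loop_suite(seed: int = 0, n_species: int = 30, n_steps: int = 1000):
    """Closed-loop Mackey–Glass generation: multiplexed simplex reservoir
    and an ESN (N = 200), both trained for one-step-ahead prediction and
    then run autonomously.  Returns
    ``{"erc": (generated, diverged), "esn": (generated, diverged)}``."""
    mg = gen_mackey_glass(n=2100)
    mu, sd = mg.u.mean(), mg.u.std()
    u, y = (mg.u - mu) / sd, (mg.y - mu) / sd

    comm = simulate_community(
        random_community_params(n_species, seed=seed), 400)
    rs = build_reservoirs(comm, seed=seed)
    states = multiplex_states([erc_run(r, u) for r in rs])
    model = train_ridge(states.matrix, y, lam=0.05, washout=50,
                        intercept=True, standardize_features=True)

    def erc_stepper(_state, uu):
        return np.concatenate([erc_step(r, uu) for r in rs])

    # fed-back input clamped to the training range, as for a physical
    # reservoir whose actuator only covers the conditions it was run under
    gen_e, _, div_e = closed_loop_generate(erc_stepper, model,
                                           states.matrix[-1], y[-1], n_steps,
                                           u_bounds=(u.min(), u.max()))

    esn = esn_init(200, 1, spectral_radius=0.95, density=0.1,
                   seed=(seed + 3) % (2**31))
    st = esn_run(esn, u)
    m2 = train_ridge(st.matrix, y, lam=0.05, washout=50, intercept=True)

    def esn_stepper(state, uu):
        return np.tanh(esn.w_in.matrix @ np.atleast_1d(uu) + esn.W @ state)

    gen_n, _, div_n = closed_loop_generate(esn_stepper, m2, st.matrix[-1],
                                           y[-1], n_steps)
    return {"erc": (gen_e, div_e), "esn": (gen_n, div_n)}


def memory_suite(seed: int = 0, n_species: int = 10, lib_len: int = 400,
                 T: int = 400, max_lag: int = 10, amplitude: float = 1.0):
    """Forgetting curves of a multiplexed simplex reservoir.

    Trains recall readouts on one uniform input sequence and tests on a
    second; the control repeats the evaluation with the input sequence
    shuffled (destroying the state–input pairing).  Also measures an ESN's
    (N = 100) memory capacity on the same protocol.
    """
    comm = simulate_community(random_community_params(n_species, seed=seed),
                              lib_len)
    utr = gen_uniform_input(T, 0, amplitude, seed=(seed * 5 + 31) % (2**31)).u
    ute = gen_uniform_input(T, 0, amplitude, seed=(seed * 5 + 32) % (2**31)).u
    str_ = multiplex_states([erc_run(r, utr)
                             for r in build_reservoirs(comm, seed=seed)])
    ste_ = multiplex_states([erc_run(r, ute)
                             for r in build_reservoirs(comm, seed=seed)])
    fc = forgetting_curve(str_.matrix, ste_.matrix, utr, ute, max_lag=max_lag)
    rng = np.random.default_rng((seed * 5 + 33) % (2**31))
    utr_s, ute_s = utr.copy(), ute.copy()
    rng.shuffle(utr_s)
    rng.shuffle(ute_s)
    fc_ctrl = forgetting_curve(str_.matrix, ste_.matrix, utr_s, ute_s,
                               max_lag=max_lag)

    esn = esn_init(100, 1, spectral_radius=0.9, density=0.1,
                   seed=(seed + 13) % (2**31))
    est = esn_run(esn, utr)
    ese = esn_run(esn, ute)
    fc_esn = forgetting_curve(est.matrix, ese.matrix, utr, ute,
                              max_lag=max_lag)
    return {"erc": fc, "erc_shuffled": fc_ctrl, "esn": fc_esn,
            "esn_units": esn.N}


def realtime_recall_suite(seed: int = 0, n_inputs: int = 256,
                          temp_range=(12.0, 24.0), lag: int = 1,
                          obs_noise_sd: float = 0.0, max_lag: int = None):
    """Six synthetic temperature-driven runs, recall of the lagged input.

    Replicate-1 runs of the three nutrient conditions form the training
    matrix (256 × 15) and replicate-2 runs the test matrix, mirroring the
    train/test protocol of a paired-run experiment.  Returns the recall
    result dict plus a shuffled-input control correlation.
    """
    temps = gen_uniform_input(n_inputs, *temp_range,
                              seed=(seed * 17 + 21) % (2**31)).u
    train_recs, test_recs = [], []
    for j, cond in enumerate(("low", "med", "high")):
        p = replace(NUTRIENT_PRESETS[cond], obs_noise_sd=obs_noise_sd,
                    seed=(seed * 29 + j) % (2**31))
        train_recs.append(simulate_driven_population(
            temps, p, condition=cond, replicate=1))
        p2 = replace(p, seed=(seed * 29 + 100 + j) % (2**31))
        test_recs.append(simulate_driven_population(
            temps, p2, condition=cond, replicate=2,
            init_p=0.8 * p.k_scale))
    train = multiplex_records(train_recs)
    test = multiplex_records(test_recs)
    out = recall_task(train, test, temps, temps, lag=lag, max_lag=max_lag)
    rng = np.random.default_rng((seed * 17 + 99) % (2**31))
    shuffled = temps.copy()
    rng.shuffle(shuffled)
    ctrl = recall_task(train, test, shuffled, shuffled, lag=lag)
    out["shuffled_r"] = ctrl["r"]
    out["train_matrix"] = train
    out["test_matrix"] = test
    return out
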