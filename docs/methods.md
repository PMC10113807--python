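# Methods

This note records the models, conventions and design choices behind
`ecoreservoir`, and what the synthetic generators do and do not emulate.

## Simplex-projection reservoir

**Embedding.** A scalar series `x` is embedded with dimension `E` and lag
`τ` into library rows `(x_t, x_{t-τ}, …, x_{t-(E-1)τ})`, most recent
coordinate first, each paired with its next-step target `x_{t+1}`; only
rows with a defined target are kept, so a series of length `n` yields
`n − 1 − (E−1)τ` rows. `E` is selected per species by leave-one-out
simplex forecasting over `E = 1…E_max` (default 10; 8 in the experiment
protocols), scoring Pearson correlation between forecasts and observed
targets; ties go to the smallest `E`, and the criterion is pluggable
(correlation or RMSE, since the convention differs between forecasting
papers). When building reservoirs we floor the result at `E = 2`: an
`E = 1` state has no lag register and therefore no memory to multiplex.

**Forecast.** `f_simp` uses the `E+1` nearest library rows by unweighted
Euclidean distance, ties broken by smaller time label for reproducibility.
Weights are `w_i = exp(−d_i/d_min)` normalised to one; when `d_min = 0`
the zero-distance neighbours share uniform weight (the 0/0 guard). The
forecast is a convex combination of neighbour targets, so it is always
bounded by the library's target range — a property the reservoir inherits.
Leave-one-out evaluation excludes only the query's own row by default; a
Theiler-style exclusion window is exposed but defaults to 0.

**State update.** `X_{t+1} = f(W_in u_t + f_simp(X_t))` with `f` the
identity ("project then add", the default; the "add then project" variant
`f_simp(X_t + W_in u_t)` is a flag). The forecast becomes coordinate 1 and
the remaining coordinates shift down the lag register; for `τ = 1` that is
a plain shift, for `τ > 1` the reservoir keeps an extended register of the
last `(E−1)τ + 1` head values, samples it every `τ`, and adds the input
weights at the sampled positions (for `τ = 1` the two formulations
coincide). Input weights are i.i.d. Uniform[−1,1] scaled by 0.3 (the
package-wide input-scaling default) with sparsity 0; how a scalar input
should be distributed across lag coordinates is not dictated by the
framework, and we use a full random `E`-vector. The initial state is the
library's last embedded vector unless overridden. A divergence guard
aborts any run whose state magnitude exceeds 1e6.

**Multiplexing.** Per-species trajectories are concatenated column-wise;
the total reservoir size is `Σ E_i` and column provenance is preserved, so
multiplexing is exactly invertible.

## Lotka–Volterra toy reservoir and ESN baseline

The LV map uses `r_x = 3.0`, `r_y = 2.7`, `β_xy = −0.2`, `β_yx = 0.2`
(the grid-searched demonstration values; the duplicated symbol in the
original parameter listing is resolved as `β_yx = 0.2`). Unforced, the
map settles on a fixed point near (0.62, 0.68) — a contracting reservoir
with fading memory. Zero is absorbing for each species (extinction), and
the reservoir equation `X_{t+1} = W_in u_t + g(X_t)` is iterated without
clipping, so inputs large enough to leave the contracting basin raise the
divergence guard; the standard demonstration therefore centres its input
to ±0.3 (see "Experiment protocols").

The ESN draws `W` i.i.d. Uniform[−1,1] with density 0.1, rescales to
spectral radius 0.95 (both config-exposed; a degenerate all-zero draw is
redrawn with the next seed and logged), uses tanh activation and the same
input-weight convention. These defaults are ordinary ESN practice; the
reference experiments this package mirrors defer their exact values to
supplementary material, so they are deliberately configurable.

## Readout

Ridge regression in closed form, `(SᵀS + λI)⁻¹Sᵀy`, after discarding a
washout (default 50 for in-silico tasks); λ defaults to 0.05. An intercept
column is used for in-silico tasks and omitted in the real-time recall
task, whose readout is exactly one weight per state column (e.g. 1×15).
Targets and, for in-silico tasks, features are z-scored with training-set
statistics stored in the model and inverted at prediction time. Feature
standardization matters: reservoir state variances vary over orders of
magnitude with the random input-weight draw, and a fixed λ otherwise
over-shrinks the readouts of weakly driven reservoirs, turning a
methodological comparison into a lottery over `W_in`. λ = 0 with a
singular design raises rather than silently pseudo-inverting.

**Closed loop.** For autonomous generation the readout output is fed back
as the next input. The fed-back value can be clamped to a given range
(`u_bounds`); the standard protocol clamps to the training input range.
This is the physical-reservoir convention — an actuator only covers the
range it was operated in — and it removes a positive-feedback failure
mode in which the linear readout extrapolates once the loop leaves the
training range. The recorded output sequence is the raw readout
(unclipped), and the divergence flag remains for unbounded use.

## Synthetic ecology

**Community generator** (stand-in for empirical multi-species series such
as fish-catch records or DNA-quantified prokaryote communities):
`x_{i,t+1} = max(0, x_i(r_i − r_i x_i + Σ_j B_ij x_j) + ε)`, the S-species
generalisation of the LV map above, with `ε ~ N(0, 0.01)` process noise.
Defaults: growth rates Uniform[2.7, 3.3] (the fluctuating regime bracketing
the toy model's own values), interactions ±Uniform(0, 0.25) present with
probability 0.3, zero diagonal, burn-in 200. What it does **not** emulate:
observation error models of real surveys, seasonality, trends, or
zero-inflation; passing tests on these communities shows the method works
on noisy nonlinear community dynamics, not that any particular empirical
dataset would certify as a reservoir.

**Driven population** (surrogate for a laboratory microbial population
under a programmable temperature regulator — whose true response function
is unknown; this is a structural stand-in, not a calibrated model). Per
fine substep (5 per input step; 256 input steps → 1280 observations):

* effective temperature: first-order lag toward the commanded value,
  `T̃ ← T̃ + a(u − T̃)` (the medium takes time to equilibrate);
* population: Ricker-logistic `p ← p·exp(r(T̃)(1 − p/K(T̃)))` with
  piecewise-linear peaked `r(T)` and `K(T)`;
* observation: `p + obs_noise_sd·√p·N(0,1)` clipped at zero (exact count
  when the noise sd is 0).

Because `0 < r < 2` throughout, the map contracts toward `K(T̃)`: two runs
with different initial populations synchronize under a common input — the
common-signal synchronization that certifies the echo state property in a
living reservoir. Three nutrient presets (low/med/high) differ in
carrying-capacity scale (120/200/320 cells per frame), growth rate
(0.15/0.45/0.9 per substep), thermal optimum (20/25/30 °C) and thermal
lag (0.25/0.5/0.85), standing in for media of increasing richness; the
spread makes the three conditions act as reservoirs with genuinely
different hyperparameters (pairwise trajectory correlations well below 1
under a common input). Not emulated: cell physiology, behaviour, imaging
artefacts, or the particle-counting step of a real rig.

## Real-time pipeline

Raw counts are detrended by LOWESS (bandwidth fraction 0.2 of the run,
linear local fits) and expressed as the relative residual
`(count − trend)/trend`, a stationary, mean-≈0 population-density index;
the smoother captures ≥95% of the variance of a noiseless logistic growth
curve while leaving input-driven fluctuations (periods ≲ tens of minutes)
intact. Time-multiplexing reshapes the 1280-sample index into 256 rows of
5 substeps; space-multiplexing concatenates runs (three conditions →
256×15; six runs → 256×30) with full provenance labels. Recall trains on
the replicate-1 runs and tests on replicate-2; the horizon sweep
multiplexes all six runs and splits temporally (first 70% train). The
recall baseline is the shuffled-input control; the forgetting-curve
baseline is the input's own autocorrelation. The horizon task's baseline
is a ridge regression of the target on the raw input value at the same λ
and split.

## Experiment protocols (and why these conditions)

All standard experiments live in `ecoreservoir.experiments`; sizes were
chosen once as the package's study conditions.

* **Lorenz prediction:** RK4 at dt = 0.01, every 20th step kept
  (0.2 time-unit sampling), 1000 samples, observable z-scored, horizon 1.
  At much finer sampling one-step prediction is nearly linear
  (lag-1 autocorrelation > 0.98) and every method saturates; at 0.2 the
  task is genuinely nonlinear (autocorrelation ≈ 0.61), which is what
  lets skill grow with the number of multiplexed species (median r ≈
  0.59 → 0.70 from 1 to 50 species in the acceptance battery).
* **Community libraries:** 400 steps for task experiments (forecastable
  attractors at moderate cost), 200 for ESP runs.
* **ESP forcing:** uniform input on [0, 3] (i.e. state perturbations up
  to ~0.9 against attractor scales near 1). The simplex map inherits the
  chaos of its source series, so the echo state property holds only when
  the common input dominates the intrinsic dynamics; under weak forcing
  some reservoirs legitimately fail to synchronize. The convergence
  summary calls a curve converged when the distance falls below 1e−3 of
  its initial value within 100 steps (pass/fail summaries use the median
  of the last 10% vs the first 10% at the same factor).
* **LV toy demonstration:** Lorenz-x min-max centred to ±0.3 at 0.05-unit
  sampling. The amplitude keeps all input-weight draws inside the map's
  contracting basin; larger excursions push the state into strongly
  nonlinear regions where linear decodability collapses.
* **NARMA:** input Uniform[0, 0.5]; NARMA2 uses the classic quadratic
  recursion (zero-input fixed point `(0.6 − √0.2)/0.8 ≈ 0.190983`),
  orders 3–10 the generic recursion with α = 0.3, β = 0.05, γ = 1.5,
  δ = 0.1 — the standard benchmark family.
* **Mackey–Glass:** β = 0.2, γ = 0.1, exponent 10, delay τ = 17 (chaotic),
  RK4 at dt = 0.1 with linear interpolation of the delayed value, sampled
  every 1.0; closed-loop training uses 2000 one-step pairs and 30
  multiplexed species (shorter training measurably destabilises the
  loop).
* **Real-time runs:** 256 coarse steps of Uniform[12, 24] °C. The band
  sits below the presets' thermal optima so the population's response is
  monotone in temperature; spanning the optima makes the response
  non-monotone, which defeats *linear* recall of the input (it remains
  exactly the regime where the reservoir beats a linear baseline at
  predicting a nonlinear function of the input, and the cross-component
  horizon experiment uses it deliberately).

## Numerical conventions

0-based indexing with original time labels carried through; knn ties
broken by smaller time label; simplex weights asserted non-negative and
summing to 1 on every call; divergence guards at 1e6 for reservoir states
and closed-loop outputs; experiment seeds derived from a single user seed
by fixed multipliers, kept below 2³¹; reports serialised with sorted keys
so identical configs give byte-identical JSON.

## Known limitations

* The simplex reservoir's ESP is forcing-dependent (see above); no claim
  is made that arbitrary ecological series yield valid reservoirs.
* Closed-loop generation reproduces bounded dynamics but not the original
  attractor — the expected behaviour for this reservoir class, reported
  as such.
* The driven-population surrogate is structural, not calibrated; its
  parameters were chosen for realism of form (contraction, inertia,
  peaked thermal response), and results on it do not quantify any real
  organism's computational capability.
* S-map, convergent cross-mapping, multivariate embeddings, trainable
  recurrent weights, and information-processing-capacity decompositions
  are out of scope.
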