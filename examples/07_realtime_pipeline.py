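"""The real-time pipeline on a simulated temperature-driven population.

Six runs (three nutrient conditions x two replicates) of a population
observed 5 times per temperature step are detrended, time-multiplexed
(256 x 5 per run) and space-multiplexed (256 x 15 per replicate set); a
1 x 15 ridge readout then recovers the temperature commanded one step
(5 minutes) earlier - the population as a thermometer with memory.
"""

import numpy as np

from ecoreservoir.experiments import realtime_recall_suite

out = realtime_recall_suite(seed=0, lag=1, obs_noise_sd=0.0, max_lag=8)
print(f"training matrix: {out['train_matrix'].matrix.shape} "
      f"(3 runs x 5 substeps)")
print(f"readout weights: {out['model'].w_out.size} (one per state column)")
print(f"\nrecall of the temperature 1 step ago: r = {out['r']:.3f}")
print(f"shuffled-input control:                r = {out['shuffled_r']:.3f}")
print("\nforgetting curve r(k) vs the input's own autocorrelation:")
for k, (r, a) in enumerate(zip(out["curve"].recall_r,
                               out["curve"].autocorrelation)):
    print(f"  lag {k}: recall {r: .3f}   autocorr {a: .3f}")
print("\nrecall above the near-zero autocorrelation baseline means the")
print("memory lives in the population dynamics, not in the input itself")
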