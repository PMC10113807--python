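"""Echo state property and forgetting curves of simplex reservoirs.

ESP: two runs of the same reservoir from different initial states must
converge when driven by the same input (and must NOT converge under
different inputs).  Memory: a readout trained to recall the input k steps
ago traces a forgetting curve r(k); its summed square over k >= 1 is the
memory capacity.
"""

import numpy as np

from ecoreservoir.experiments import esp_suite, memory_suite

esp = esp_suite(n_species=10, seed=0)
conv = sum(r["converged"] for r in esp)
ctrl = sum(r["control_ratio"] > 0.1 for r in esp)
print(f"ESP: {conv}/10 reservoirs synchronized under a common input")
print(f"     {ctrl}/10 kept distinct states under different inputs (control)")

mem = memory_suite(seed=0)
print("\nforgetting curve r(k), simplex reservoir vs shuffled control:")
for k in range(6):
    print(f"  lag {k}: r = {mem['erc'].recall_r[k]:.3f}   "
          f"shuffled = {mem['erc_shuffled'].recall_r[k]:.3f}")
print(f"reservoir memory capacity: {mem['erc'].memory_capacity:.2f}")
print(f"ESN (N={mem['esn_units']}) memory capacity: "
      f"{mem['esn'].memory_capacity:.2f} (bounded by N)")
print("\nrecall far above the shuffled control at small lags shows the")
print("states genuinely store recent inputs, not chance correlations")
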