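"""NARMA2 emulation by a species-multiplexed simplex reservoir.

The reservoir is driven by the NARMA input sequence and the readout learns
the NARMA2 response; an input-only ridge regression is the baseline.  The
analytic fixed point of the NARMA2 recursion under zero input is printed
as a correctness anchor.
"""

import numpy as np

from ecoreservoir.experiments import narma_emulation
from ecoreservoir.tasks import NARMA2_FIXED_POINT, gen_narma

fp = gen_narma(2, np.zeros(500)).y[-1]
print(f"NARMA2 zero-input fixed point: simulated {fp:.9f}, "
      f"analytic {NARMA2_FIXED_POINT:.9f}")

res, base = narma_emulation(order=2, n_species=20, seed=0)
print(f"\nNARMA2 emulation NMSE (held-out 30%):")
print(f"  multiplexed reservoir: {res:.4f}")
print(f"  input-only ridge:      {base:.4f}")
print("the baseline is near 1 (no better than the mean) because NARMA2")
print("depends nonlinearly on input history, which the reservoir carries")
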