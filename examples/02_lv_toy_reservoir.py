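"""A two-species Lotka-Volterra map as a working reservoir.

The toy model x' = x(r_x - r_x x + b_xy y), y' = y(r_y - r_y y + b_yx x)
receives a scaled Lorenz signal through random input weights; a ridge
readout on its 2-dimensional state predicts the signal one step ahead and
is compared with ridge regression on the raw input alone.
"""

import numpy as np

from ecoreservoir.experiments import lv_vs_baseline

pairs = lv_vs_baseline(n_seeds=10, seed=0)
wins = sum(res < base for res, base in pairs)
print("one-step Lorenz prediction NMSE, 10 input-weight draws:")
for i, (res, base) in enumerate(pairs):
    print(f"  draw {i}: reservoir {res:.4f}  vs  input-only ridge {base:.4f}")
print(f"\nreservoir wins {wins}/10 draws")
print("the 2-unit ecological reservoir holds a short input history that")
print("the memoryless baseline cannot use")
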