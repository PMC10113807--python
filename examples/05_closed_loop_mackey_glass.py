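"""Closed-loop generation of Mackey-Glass dynamics.

Reservoirs are trained to predict the chaotic Mackey-Glass series one step
ahead, then run autonomously with their own output fed back as input.  The
echo state network reproduces bounded chaotic-looking dynamics; the
multiplexed ecological reservoir also stays bounded but generates
different attractor dynamics rather than reproducing the original.
"""

import numpy as np

from ecoreservoir.experiments import closed_loop_suite

out = closed_loop_suite(seed=0, n_steps=1000)
for name, (gen, diverged) in out.items():
    tail = gen[-500:]
    print(f"{name.upper()}: diverged={diverged}, steps={len(gen)}, "
          f"range [{gen.min():.2f}, {gen.max():.2f}], "
          f"sd(last 500) = {np.std(tail):.3f}")
print("\nboth loops stay bounded for 1000 autonomous steps (the training")
print("signal is z-scored, so sd near 1 means lively ongoing dynamics);")
print("matching the original attractor is not expected for the ecological")
print("reservoir - it generates its own")
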