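"""Delay embedding and simplex projection on a synthetic community series.

Reconstructs the state space of one species' abundance series, picks the
embedding dimension by leave-one-out forecast skill, and forecasts a few
held-out points by the weighted average of nearest-neighbour futures.
"""

import numpy as np

from ecoreservoir.embedding import (embed, select_embedding_dimension,
                                    simplex_forecast)
from ecoreservoir.synthetic import random_community_params, simulate_community

community = simulate_community(random_community_params(5, seed=1), 400)
x = community[:, 0]

E_star, skills = select_embedding_dimension(x[:300], E_max=8)
print(f"embedding dimension selected: E = {E_star}")
print("leave-one-out forecast skill (Pearson r) per E:")
for E, s in skills.items():
    print(f"  E={E}: {s:.3f}")

emb = embed(x[:300], E_star)
errors = []
for t in range(300, 380):
    query = x[t - E_star + 1: t + 1][::-1]  # most recent coordinate first
    pred = simplex_forecast(emb, query)
    errors.append(abs(pred - x[t + 1]))
print(f"\nout-of-library one-step forecasts, n={len(errors)}:")
print(f"  mean |error| = {np.mean(errors):.4f}  (series sd = {x.std():.4f})")
print("a mean error well below the series sd means the reconstructed")
print("attractor captures the deterministic part of the dynamics")
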