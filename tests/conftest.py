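import numpy as np
import pytest

from ecoreservoir.embedding import embed
from ecoreservoir.synthetic import random_community_params, simulate_community


@pytest.fixture(scope="session")
def logistic_series():
    """Chaotic logistic-map series (r = 3.8), a standard embedding testbed."""
    x = np.empty(300)
    x[0] = 0.2
    for t in range(299):
        x[t + 1] = 3.8 * x[t] * (1.0 - x[t])
    return x


@pytest.fixture(scope="session")
def logistic_embedding(logistic_series):
    return embed(logistic_series, E=2, tau=1)


@pytest.fixture(scope="session")
def small_community():
    """(200, 5) community table used by reservoir-level tests."""
    params = random_community_params(5, seed=42)
    return simulate_community(params, 200)
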