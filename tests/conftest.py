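import numpy as np
import pytest

from ppdnet.datasets import default_two_group_config, generate_cohort
from ppdnet.ising import IsingNetwork


@pytest.fixture(scope="session")
def matched_cohort():
    """Cohort at the study's scale: n=372, 10% post-baseline missingness."""
    cfg = default_two_group_config(n_subjects=372, missing_rate=0.1, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def chain_truth():
    """Ten-node chain Ising network with unit couplings, tau = -1."""
    p = 10
    w = np.zeros((p, p))
    for i in range(p - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return IsingNetwork(np.full(p, -1.0), w,
                        [f"item{i}" for i in range(1, p + 1)])
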