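import numpy as np
import pytest

from dfcdist import SimConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_connectivity(rng, m):
    """Random symmetric hollow matrix with entries in [0, 1]."""
    upper = rng.uniform(0.0, 1.0, size=(m, m))
    mat = np.triu(upper, 1)
    mat = mat + mat.T
    return mat


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small deterministic cohort reused across tests (12 subjects)."""
    cfg = SimConfig(n_per_cell=2, n_regions=6, n_timepoints=90, seed=7)
    return cfg, generate_cohort(cfg)
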