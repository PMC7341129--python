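import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from usfsdfe import make_dfe, sample_poisson_usfs


@pytest.fixture(scope="session")
def std_ddfe():
    """The study's deleterious DFE: gamma, shape 0.3, mean 2N_e*s = -2000."""
    return make_dfe(0.3, -2000.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def mild_full_dfe():
    """Mild, frequent beneficials: the regime where the uSFS is informative."""
    return make_dfe(0.3, -2000.0, 0.01, 10.0)


@pytest.fixture(scope="session")
def full_scale_dataset(mild_full_dfe):
    """One Poisson uSFS dataset at the full-study site counts."""
    return sample_poisson_usfs(mild_full_dfe, 40, 0.01, 14e6, 7e6,
                               delta_neut=0.05, with_divergence=True, seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
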