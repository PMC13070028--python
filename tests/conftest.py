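import numpy as np
import pytest

from connrel import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_cohort():
    """10 subjects x 2 scanners x 190 edges, FC-like, with batch distortion."""
    return simulate_cohort(SimConfig(n_regions=20, rng_seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Same size, no batch distortion, no covariate effects."""
    return simulate_cohort(SimConfig(n_regions=20, rng_seed=12, batch=None))
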