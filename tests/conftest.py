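import numpy as np
import pytest

from idscn import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Small cohort for fast structural tests (not the study conditions)."""
    return SimConfig(n_per_group=12, n_regions=12, n_modules=3, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the study conditions (51 per group, 34 regions)."""
    return simulate_cohort(SimConfig(seed=2024))
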