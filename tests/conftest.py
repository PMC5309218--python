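import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rewardmem as rm

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_design():
    return rm.generate_session_design(seed=1)


@pytest.fixture(scope="session")
def table1_params():
    """Published 20-min group means of the signed-PE + expected-value model."""
    return rm.group_mean_params("pe_ev", "20min")


@pytest.fixture(scope="session")
def small_cohort(table1_params):
    """25 simulated participants at the published group means."""
    return rm.simulate_cohort(25, "pe_ev", table1_params, base_seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
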