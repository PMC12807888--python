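import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import affectbandit as ab

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_script():
    return ab.make_default_script(8, seed=0)


@pytest.fixture
def default_profile():
    """A mid-trait simulated user from the default cohort settings."""
    return ab.make_profile(ab.CohortSpec(), "u01", trait=16.0)


@pytest.fixture
def high_trait_profile():
    return ab.make_profile(ab.CohortSpec(), "u02", trait=28.0)
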