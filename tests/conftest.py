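import pytest
from hypothesis import HealthCheck, settings

import lh2bend as lb

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def flat_ring():
    """The default 18-site B850 ring (r0 = 3.8 nm, +/-10 deg alternation)."""
    return lb.build_ideal_ring()


@pytest.fixture
def small_disorder():
    """A cheap disorder ensemble for unit tests."""
    return lb.DisorderModel(gamma=125.0, n_realizations=100, seed=7)
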