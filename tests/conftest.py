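import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from motion_forecast import default_observer

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def observer():
    """The packaged calibrated observer."""
    return default_observer()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
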