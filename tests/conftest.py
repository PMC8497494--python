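import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ratiovm.models import CALIBRATIONS

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rasap():
    """Canonical (orientation-corrected) rASAP Boltzmann calibration."""
    return CALIBRATIONS["rASAP"]


@pytest.fixture
def rarc():
    return CALIBRATIONS["rArc"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
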