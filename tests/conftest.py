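import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def acute_regimen():
    from pdtrace.synthetic import ACUTE_REGIMEN

    return ACUTE_REGIMEN


@pytest.fixture
def default_rates():
    from pdtrace.synthetic import TransitRates

    return TransitRates()


@pytest.fixture
def small_truth_map():
    return np.array([[0.5, 0.0], [1.0, 2.0]])


@pytest.fixture
def strong_reference():
    """Reference-target settings with negligible calibration uncertainty."""
    return {"reference_areal_masses_ug_cm2": (20.0,), "reference_dwell_s": 100.0}
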