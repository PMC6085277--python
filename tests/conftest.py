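import pytest
from hypothesis import HealthCheck, settings

from vvecmo import BloodSpec, ModelInputs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec10():
    """Standard patient blood: Hb 10 g/dl, 37 degC, no P50 shift."""
    return BloodSpec(hb=10.0)


@pytest.fixture(scope="session")
def spec15():
    return BloodSpec(hb=15.0)


@pytest.fixture(scope="session")
def healthy_inputs():
    """Calibrated zero-shunt lung with no extracorporeal exchange."""
    return ModelInputs(shunt_fraction=0.0, ve=6.157, va=None, vd=0.3 * 6.157)
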