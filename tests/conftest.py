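import pytest
from hypothesis import HealthCheck, settings

# one deterministic profile for the whole suite
settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def clinical_design():
    """Continuous design with the study's clinical parameters."""
    from lccusum import build_design

    return build_design(0.10, 0.05, signal_limit=0.74, horizon=50)


@pytest.fixture
def integer_design():
    from lccusum import default_integer_design

    return default_integer_design()
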