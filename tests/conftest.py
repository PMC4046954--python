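import pytest
from hypothesis import HealthCheck, settings

import larvaforage as lf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def builtins():
    return {t.name: t for t in lf.builtin_types()}


@pytest.fixture(scope="session")
def calibrated():
    """Model config with the shipped respiration calibration (finite growth)."""
    return lf.calibrated_config()


@pytest.fixture(scope="session")
def calm():
    """A bland calm-water environment for foraging-geometry checks."""
    return lf.Environment(T=10.0, photoperiod=12.0, epsilon=0.0, b_total=5.0, s=-1.2)


@pytest.fixture(scope="session")
def small_cfg():
    """A 12-bin prey domain for exhaustive-subset diet oracles."""
    return lf.ModelConfig(bin_lo=0.04, bin_hi=0.16, bin_width=0.01)
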