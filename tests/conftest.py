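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

from g4pull.constants import PhysicalConstants  # noqa: E402
from g4pull.presets import clamp_model, dwell_rate_set  # noqa: E402


@pytest.fixture(scope="session")
def consts():
    return PhysicalConstants()


@pytest.fixture(scope="session")
def kbt(consts):
    return consts.kbt


@pytest.fixture(scope="session")
def model_5pn():
    """Sequential U/S/L model calibrated at the 5 pN dwell constants."""
    return clamp_model(5.0, include_ul=False)


@pytest.fixture(scope="session")
def rates_5pn():
    return dwell_rate_set(5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140710)
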