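import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nativedg import ThermoCondition

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def cond25():
    return ThermoCondition(25.0, "PBS")


@pytest.fixture
def cond25_mg():
    return ThermoCondition(25.0, "TE 12.5 mM Mg2+")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
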