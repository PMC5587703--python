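import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tidalox import (
    GasExchangeParams,
    RespiratoryMechanics,
    VentilatorSettings,
    simulate_tidal,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mech() -> RespiratoryMechanics:
    return RespiratoryMechanics()


@pytest.fixture(scope="session")
def params() -> GasExchangeParams:
    return GasExchangeParams()


@pytest.fixture(scope="session")
def vc_rr12_settings() -> VentilatorSettings:
    """The reference tidal condition: VC, RR 12, I:E 1:1, 10 ml/kg, PEEP 5."""
    return VentilatorSettings(
        mode="VC", rr=12, ie_ratio=1.0, vt=290.0, peep=5.0, fio2=0.33
    )


@pytest.fixture(scope="session")
def vc_rr12_trace(vc_rr12_settings, mech, params):
    """A 3-min reference simulation (1-min transient + 2-min window)."""
    return simulate_tidal(vc_rr12_settings, mech, params, duration=180.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
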