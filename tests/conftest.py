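import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ciliapump import CiliaParams, PumpState, pumping_integrals


@pytest.fixture(scope="session")
def base_params() -> CiliaParams:
    """The workhorse parameter set of the published figures."""
    return CiliaParams(epsilon=0.25, alpha=0.4, beta=0.4, hp=0.0)


@pytest.fixture(scope="session")
def casson_params() -> CiliaParams:
    return CiliaParams(epsilon=0.25, alpha=0.4, beta=0.4, hp=0.05)


@pytest.fixture(scope="session")
def trapping_pump(casson_params):
    """Operating point of the streamline panels (Qbar = 0.95)."""
    ints = pumping_integrals(casson_params)
    return PumpState.from_qbar(0.95, casson_params, ints)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20150219)
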