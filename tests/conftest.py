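import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from aersim.process_model import ProcessParams, ProcessState


@pytest.fixture(scope="session")
def default_params() -> ProcessParams:
    return ProcessParams.default()


@pytest.fixture(scope="session")
def oracle_params() -> ProcessParams:
    """Round-number parameter set used by the frozen arithmetic oracles."""
    return ProcessParams(
        eta=0.6,
        k_resp=0.005,
        k_max=0.2,
        k_s=60.0,
        lam=0.125,
        k_d=0.0025,
        s_in=400.0,
        o_sat=9.08,
        k_air=0.25,
        mu_max=100.0,
    )


@pytest.fixture()
def mid_state() -> ProcessState:
    return ProcessState(O=2.0, S=100.0, X=2600.0)
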