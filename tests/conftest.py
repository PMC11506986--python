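import pytest
from hypothesis import HealthCheck, settings

import epime as e

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def sis_params():
    """The reference SIS parameter set (beta=0.6, gamma=0.1) at small N."""
    return e.EpidemicParams(beta=0.6, gamma=0.1, N=10, model=e.Model.SIS)


@pytest.fixture
def sir_params():
    return e.EpidemicParams(beta=0.6, gamma=0.1, N=10, model=e.Model.SIR)


@pytest.fixture
def sir_space(sir_params):
    return e.build_state_space(sir_params)


def make_system(beta, gamma, N, model):
    """Params + state space + generator in one call."""
    params = e.EpidemicParams(beta=beta, gamma=gamma, N=N, model=model)
    space = e.build_state_space(params)
    return params, space, e.build_generator(params, space)
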