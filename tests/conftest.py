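import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def exp2_design():
    from lightzones import experiment2_design

    return experiment2_design()


@pytest.fixture(scope="session")
def exp1_design_and_grids():
    from lightzones import experiment1_design

    return experiment1_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
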