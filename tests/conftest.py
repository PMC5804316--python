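import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def registry():
    from bnetbench import DEFAULT_REGISTRY

    return DEFAULT_REGISTRY


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_profile(compound="drug", **block):
    from bnetbench import BlockProfile

    return BlockProfile(compound=compound, block=block)


@pytest.fixture
def full_profile():
    # one compound active on all seven currents
    return make_profile(
        IKr=0.4, IKs=0.1, Ito=0.05, ICaL=0.2, INa_peak=0.05, INa_late=0.1, IK1=0.0
    )
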