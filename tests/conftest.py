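import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def simple_scenario():
    from gsnkit import make_simple_scenario

    return make_simple_scenario()


@pytest.fixture(scope="session")
def simple_dataset():
    """One medium-sized dataset from the simple scenario, shared across
    tests that only need plausible structured input."""
    from gsnkit import make_simple_scenario, synthesize

    return synthesize(make_simple_scenario(), c=200, t=5, seed=777)
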