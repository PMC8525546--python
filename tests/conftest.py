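import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cpast.environment import GridSpec, build_vase

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid30():
    return GridSpec(30, 30)


@pytest.fixture(scope="session")
def vases(grid30):
    """One stimulus per decoration-complexity level on the default grid."""
    return {c: build_vase(c, grid30) for c in range(4)}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
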