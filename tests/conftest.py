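import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from quadlaw.datasets import lvhua_macroalgae

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """The packaged 15-species published summary (p, epsilon, delta)."""
    return lvhua_macroalgae()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
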