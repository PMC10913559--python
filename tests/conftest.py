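import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240304)


@pytest.fixture
def random_compositions(rng):
    """1000 strictly positive random 4-part compositions closed to 1440."""
    logits = rng.normal(scale=1.5, size=(1000, 4))
    parts = np.exp(logits)
    return parts * (1440.0 / parts.sum(axis=1, keepdims=True))
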