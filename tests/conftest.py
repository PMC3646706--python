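import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    """Fresh, deterministically seeded generator for each test."""
    return np.random.default_rng(20260928)


@pytest.fixture
def make_rng():
    def _make(seed):
        return np.random.default_rng(seed)

    return _make
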