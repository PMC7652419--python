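import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neuropheno import synthetic as syn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def truth() -> syn.GroundTruth:
    """Default study-condition ground truth with a fixed seed."""
    return syn.GroundTruth(seed=12345)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)
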