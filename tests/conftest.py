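import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_axis():
    """A coarse ascending test axis covering the full bucketing range."""
    return np.linspace(0.0, 10.0, 20001)  # 5e-4 ppm step
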