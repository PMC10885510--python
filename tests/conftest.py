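import numpy as np
import pytest

from fiberphot import Recording


@pytest.fixture
def simple_recording():
    """7 samples at 1 Hz with a binary TTL channel and a ramp signal."""
    t = np.arange(7.0)
    return Recording(
        "simple", t,
        {"ttl": np.array([0, 0, 1, 1, 0, 1, 0], dtype=float),
         "sig": np.arange(7.0) * 2.0},
        1.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
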