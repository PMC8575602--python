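import numpy as np
import pytest

from topoeeg import SessionConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast-to-generate session: 6 channels, 3 RSD + 2 GST trials."""
    return SessionConfig(n_channels=6, n_rsd_trials=3, n_gst_trials=2,
                         stimulus_s=2.0, seed=11)
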