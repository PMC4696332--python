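import numpy as np
import pytest

from alphaband.channels import CANONICAL_19
from alphaband.io import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(samples, fs=250.0, channels=None):
    if channels is None:
        channels = list(CANONICAL_19[: samples.shape[0]])
    return Recording(samples=samples, fs=fs, channels=channels)


@pytest.fixture
def sine_recording():
    """19-channel, 60 s recording: 20 µV 10 Hz sinusoid + tiny offset noise."""
    t = np.arange(0, 60, 1 / 250)
    base = 20 * np.sin(2 * np.pi * 10 * t)
    g = np.random.default_rng(0)
    data = np.vstack([base + g.normal(0, 0.1, t.size) for _ in range(19)])
    return make_recording(data)
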