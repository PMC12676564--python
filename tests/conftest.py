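import numpy as np
import pytest

from dmdeeg.epochs import Epoch
from dmdeeg.io import EEGRecording, StimulusInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def epoch_24s(rng):
    """A 24-s, 19-channel epoch of band-limited signal + noise at 500 Hz."""
    fs = 500.0
    t = np.arange(int(24 * fs)) / fs
    data = (np.outer(np.linspace(0.5, 2.0, 19), np.sin(2 * np.pi * 10 * t))
            + 0.3 * rng.standard_normal((19, t.size)))
    return Epoch("S000", 0, 0.0, data, fs)


@pytest.fixture
def small_recording(rng):
    """A 40-s, 4-channel recording with a [2, 38] s stimulus interval."""
    fs = 250.0
    t = np.arange(int(40 * fs)) / fs
    data = (np.outer([1.0, 0.5, 2.0, 1.5], np.sin(2 * np.pi * 8 * t))
            + 0.2 * rng.standard_normal((4, t.size)))
    rec = EEGRecording("S000", "CN", data, fs)
    return rec, StimulusInterval("S000", 2.0, 38.0)
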