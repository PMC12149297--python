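import numpy as np
import pytest

from eegrc.io import ALL19, Recording
from eegrc.preprocess import Epoch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def montage_recording(rng):
    """A 19-channel, 60 s, 500 Hz white-noise recording (10 uV RMS)."""
    data = 10.0 * rng.standard_normal((19, 30000))
    return Recording(data=data, fs=500.0, channels=list(ALL19),
                     subject_id="sub-test", group="control")


def make_epoch(data, fs=500.0, channels=None, **kw):
    channels = channels or [f"ch{i}" for i in range(data.shape[0])]
    return Epoch(data=np.asarray(data, float), fs=fs, channels=channels, **kw)


@pytest.fixture
def tone_epoch():
    """15 s single-channel unit-amplitude 10 Hz sinusoid at 500 Hz."""
    t = np.arange(7500) / 500.0
    return make_epoch(np.sin(2 * np.pi * 10 * t)[None, :])
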