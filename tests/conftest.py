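import numpy as np
import pytest

from eegcog.preprocess import CHANNELS_1020, EEGRecording, EpochedEEG


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_recording(rng):
    data = 10.0 * rng.standard_normal((19, 250 * 60))
    return EEGRecording(data, CHANNELS_1020, 250.0, "noise")


def make_epochs(data_3d, sfreq=250.0, labels=None):
    n_ch = data_3d.shape[1]
    return EpochedEEG(
        epochs=np.asarray(data_3d, dtype=float),
        sfreq=sfreq,
        epoch_length=data_3d.shape[2] / sfreq,
        overlap=0.0,
        rejection_log=[],
        channel_labels=labels or [f"ch{i}" for i in range(n_ch)],
    )


@pytest.fixture
def sinusoid_epochs():
    """Four 4-s epochs of a unit-amplitude 10 Hz sinusoid on one channel."""
    t = np.arange(1000) / 250.0
    x = np.sin(2 * np.pi * 10 * t)
    return make_epochs(np.tile(x, (4, 1, 1)))
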