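import numpy as np
import pytest

from eegquad.containers import EEGEpoch
from eegquad.montage import KEY11_CHANNELS
from eegquad.simulate import SyntheticDesign, gen_eeg, gen_ratings, truth_to_labels


def make_epoch(signals, fs=128.0, channels=None, **kw):
    """Build an EEGEpoch from a channels x samples array with default names."""
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if channels is None:
        channels = KEY11_CHANNELS[: signals.shape[0]]
    return EEGEpoch(signals, tuple(channels), fs, **kw)


def tone_epoch(freq_hz, fs=128.0, duration=60.0, n_channels=1, amplitude=1.0):
    """Pure sinusoid replicated on every channel."""
    t = np.arange(int(duration * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return make_epoch(np.tile(x, (n_channels, 1)), fs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def key11_noise_epoch():
    """60 s of white noise on the full reduced montage."""
    gen = np.random.default_rng(7)
    return make_epoch(gen.standard_normal((11, 60 * 128)))


@pytest.fixture(scope="session")
def boosted_epochs():
    """Eight short synthetic epochs, two per class, default one-band-boost gains."""
    design = SyntheticDesign(
        n_subjects=2, n_videos=4, duration=8.0, artifact_rate=0.0, seed=11
    )
    _, truth = gen_ratings(design)
    labels = truth_to_labels(truth, range(2))
    epochs = gen_eeg(labels, design)
    return epochs, labels, design
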