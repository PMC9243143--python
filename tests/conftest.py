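import numpy as np
import pytest

from eegsonify import synthdata as sd
from eegsonify.io_formats import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_record():
    """120 s, 4-channel synthetic record with one mid-record seizure."""
    cfg = sd.SynthConfig(
        duration=120.0, n_channels=4,
        events=[sd.SeizureEventSpec(onset=40.0, duration=30.0, f_start=3.0,
                                    f_end=1.5, rms=67.8, channels=(0, 1))],
        ecg=sd.EcgSpec(), seed=7)
    return sd.gen_record(cfg)


@pytest.fixture(scope="session")
def background_record():
    """60 s of pure colored-noise background, 3 channels."""
    cfg = sd.SynthConfig(duration=60.0, n_channels=3, seed=11)
    rec, _ = sd.gen_record(cfg)
    return rec


def make_sine_recording(freq=2.0, amplitude=1.0, duration=10.0, rate=256.0,
                        n_channels=1):
    t = np.arange(int(duration * rate)) / rate
    x = amplitude * np.sin(2 * np.pi * freq * t)
    samples = np.tile(x, (n_channels, 1))
    labels = [f"S{i}" for i in range(n_channels)]
    return Recording(labels, rate, samples)
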