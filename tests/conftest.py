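import numpy as np
import pytest

from ripplelock.core import TimeSeries
from ripplelock.simulate import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def desk_recording():
    """Detector-stress profile: 60 s, 30 complexes at 4 kHz."""
    cfg = SynthConfig.desk(seed=1)
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def sparse_recording():
    """Analysis profile: 90 s, 12 complexes — leaves event-free baseline."""
    cfg = SynthConfig.desk(seed=2, duration=90.0, n_complexes=12)
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_sine(freq, fs=1000.0, duration=2.0, amp=1.0):
    t = np.arange(0, duration, 1.0 / fs)
    return TimeSeries(amp * np.cos(2 * np.pi * freq * t), fs)
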