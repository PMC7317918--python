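import numpy as np
import pytest

from cardiocoh import SyntheticConfig, UniformSignal, WaveletParams


def make_tone(freq: float, fs: float, duration: float, phase: float = 0.0,
              amp: float = 1.0, label: str = "tone") -> UniformSignal:
    t = np.arange(int(round(fs * duration))) / fs
    return UniformSignal(samples=amp * np.sin(2 * np.pi * freq * t + phase),
                         fs=fs, label=label)


@pytest.fixture
def tone():
    return make_tone


@pytest.fixture
def fast_cfg():
    """Short low-rate recording config for replicate-style tests."""
    return SyntheticConfig(duration_s=600.0, fs=4.0, seed=0)


@pytest.fixture
def band_params():
    """Modulation-band-limited transform (cheap surrogate loops)."""
    return WaveletParams(fmin=0.03, fmax=0.15)


@pytest.fixture
def low_params():
    """Low-frequency transform covering respiration and modulation bands."""
    return WaveletParams(fmin=0.02, fmax=0.6)
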