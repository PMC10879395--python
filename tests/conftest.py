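import numpy as np
import pytest

from ripplepac import LfpRecording
from ripplepac.synthetic import RippleConfig, SyntheticConfig, generate

FS = 1000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone():
    """Factory for pure-tone recordings: tone(freq, duration_s, amp)."""

    def make(freq: float, duration_s: float = 4.0, amp: float = 1.0, fs: float = FS):
        t = np.arange(int(duration_s * fs)) / fs
        return LfpRecording(amp * np.cos(2 * np.pi * freq * t), fs)

    return make


@pytest.fixture
def ripple_session():
    """60 s synthetic session with fixed 40 ms ripples at 0.2 Hz, seed 7."""
    cfg = SyntheticConfig(
        duration_s=60.0,
        seed=7,
        ripples=RippleConfig(rate=0.2, duration_ms=40.0),
    )
    return generate(cfg)
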