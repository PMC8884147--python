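import numpy as np
import pytest

from respiqual.core import Segment
from respiqual.synth import generate_dataset, uniform_protocol

FS = 16.0


def sinusoid_segment(freq_hz: float, duration_s: float = 60.0, fs: float = FS,
                     amplitude: float = 1.0, phase: float = 0.0) -> Segment:
    t = np.arange(int(duration_s * fs)) / fs
    return Segment(
        samples=amplitude * np.sin(2 * np.pi * freq_hz * t + phase),
        fs=fs,
        recording_id="sine",
    )


@pytest.fixture
def clean_sine() -> Segment:
    """0.25 Hz sinusoid, 60 s at 16 Hz: an idealized clean breathing segment."""
    return sinusoid_segment(0.25)


@pytest.fixture
def white_noise() -> Segment:
    rng = np.random.default_rng(42)
    return Segment(samples=rng.standard_normal(960), fs=FS, recording_id="noise")


@pytest.fixture(scope="session")
def breathing_segment():
    """A realistic clean synthetic breathing segment (60 s, ~13 breaths/min)."""
    ds = generate_dataset(
        1, uniform_protocol("Sp", 120.0, rate_range=(12, 14)), {}, seed=9, seg_len_s=60.0
    )
    return ds.segments[0]
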