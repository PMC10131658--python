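from datetime import datetime

import numpy as np
import pytest

from walkanchor import IntensityCutPoints, PipelineConfig, TriaxialRecording

T0 = datetime(2024, 3, 4, 0, 0, 0)


@pytest.fixture
def cuts() -> IntensityCutPoints:
    return IntensityCutPoints()


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def gravity_recording() -> TriaxialRecording:
    """60 s of pure gravity on z at 50 Hz — a motionless, noiseless device."""
    n = 60 * 50
    samples = np.zeros((n, 3))
    samples[:, 2] = 1.0
    return TriaxialRecording("wrist", 50.0, T0, samples)


def make_recording(samples: np.ndarray, fs: float = 50.0, site: str = "wrist",
                   start=T0) -> TriaxialRecording:
    return TriaxialRecording(site, fs, start, samples)


def sinusoid_recording(
    amplitude_g: float,
    freq_hz: float,
    duration_s: float = 60.0,
    fs: float = 50.0,
    axis: int = 0,
    gravity_axis: int = 2,
    site: str = "wrist",
) -> TriaxialRecording:
    """Gravity on one axis plus a sinusoid on another."""
    t = np.arange(int(duration_s * fs)) / fs
    samples = np.zeros((len(t), 3))
    samples[:, gravity_axis] = 1.0
    samples[:, axis] += amplitude_g * np.sin(2 * np.pi * freq_hz * t)
    return TriaxialRecording(site, fs, T0, samples)
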