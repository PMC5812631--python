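"""Shared fixtures and signal builders for the test suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cprfb import AccelerationRecord, RunConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

FS = 250.0


def sine_accel_amplitude(depth_mm: float, rate_cpm: float) -> float:
    """Acceleration amplitude (m/s²) of a sinusoidal compression.

    A sinusoidal displacement of peak-to-peak ``depth_mm`` at ``rate_cpm``
    has acceleration amplitude (depth/2) * (2*pi*f)^2.
    """
    omega = 2.0 * np.pi * rate_cpm / 60.0
    return (depth_mm / 2.0 / 1000.0) * omega**2


def make_sine_record(
    depth_mm: float,
    rate_cpm: float,
    duration_s: float = 2.0,
    fs: float = FS,
    phase: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> AccelerationRecord:
    """Acceleration record of a pure sinusoidal compression series."""
    t = np.arange(int(round(duration_s * fs))) / fs
    a = sine_accel_amplitude(depth_mm, rate_cpm) * np.cos(
        2.0 * np.pi * rate_cpm / 60.0 * t + phase
    )
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        a = a + rng.normal(0.0, noise_sd, a.size)
    return AccelerationRecord(samples=a, fs=fs)


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
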