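"""Windowing and compression-activity detection.

The acceleration stream is cut into non-overlapping analysis windows
(2 s by default).  Each window is linearly detrended — removing DC sensor
offset and slow baseline drift — and classified as a *compression window*
when its power (mean squared acceleration) exceeds a fixed threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend

from .io import AccelerationRecord

__all__ = [
    "AnalysisWindow",
    "DetectionResult",
    "segment_windows",
    "window_power",
    "classify_window",
]


@dataclass(frozen=True)
class AnalysisWindow:
    """One detrended analysis window of the acceleration signal."""

    index: int
    t_start: float
    samples: np.ndarray  # detrended, m/s²
    fs: float


@dataclass(frozen=True)
class DetectionResult:
    index: int
    power: float  # (m/s²)²
    is_compression: bool


def segment_windows(record: AccelerationRecord, window_s: float = 2.0) -> list[AnalysisWindow]:
    """Cut a record into contiguous non-overlapping detrended windows.

    The trailing partial window (fewer than ``window_s * fs`` samples) is
    discarded.  Each window has its best-fit linear trend removed, so a
    constant or ramp input becomes (numerically) zero.
    """
    n_win = int(round(window_s * record.fs))
    if n_win < 4:
        raise ValueError("window too short: window_s * fs must be at least 4 samples")
    n_windows = record.samples.size // n_win
    windows = []
    for i in range(n_windows):
        seg = record.samples[i * n_win : (i + 1) * n_win]
        seg = detrend(seg, type="linear")
        windows.append(
            AnalysisWindow(
                index=i,
                t_start=record.start_time + i * n_win / record.fs,
                samples=seg,
                fs=record.fs,
            )
        )
    return windows


def window_power(window: AnalysisWindow) -> float:
    """Mean squared acceleration of a detrended window, in (m/s²)²."""
    return float(np.mean(window.samples**2))


def classify_window(window: AnalysisWindow, power_threshold: float = 0.34) -> DetectionResult:
    """Label a window as compression iff its power strictly exceeds the threshold."""
    if power_threshold < 0:
        raise ValueError("power_threshold must be non-negative")
    p = window_power(window)
    return DetectionResult(index=window.index, power=p, is_compression=p > power_threshold)
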