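"""Displacement reconstruction and per-window feedback values.

Each spectral component of the acceleration is double-integrated in closed
form: a harmonic ``a_k cos(2π f_k t + φ_k)`` corresponds to the displacement
harmonic ``a_k / (2π f_k)² · cos(2π f_k t + φ_k + π)`` (the π term is the
sign flip of dividing by ``−ω²``).  Summing the K components gives the
periodic *average compression signal* of the window; compression depth is
its peak-to-peak value in mm and compression rate is ``60 · f_cc`` in cpm.
Per-window segments concatenate into a full-episode displacement estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .io import AccelerationRecord, RunConfig
from .spectral import (
    HarmonicModel,
    NoSpectralPeakError,
    compute_spectrum,
    estimate_fundamental,
    extract_harmonics,
)
from .windowing import AnalysisWindow, classify_window, segment_windows

__all__ = [
    "DisplacementSegment",
    "WindowEstimate",
    "synthesize_displacement",
    "depth_from_segment",
    "rate_from_fundamental",
    "process_window",
    "process_episode",
    "oracle_double_integration",
]

logger = logging.getLogger("cprfb")


@dataclass(frozen=True)
class DisplacementSegment:
    """Reconstructed chest displacement, mm, negative = downward."""

    values: np.ndarray
    fs: float
    t_start: float = 0.0


@dataclass(frozen=True)
class WindowEstimate:
    """Per-window feedback output of the algorithm."""

    index: int
    t_start: float
    power: float
    detected: bool
    depth_mm: float | None
    rate_cpm: float | None
    model: HarmonicModel | None
    segment: DisplacementSegment


def synthesize_displacement(
    model: HarmonicModel, duration_s: float, fs: float, t_start: float = 0.0
) -> DisplacementSegment:
    """Fourier-series displacement of a harmonic acceleration model, in mm."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    s = np.zeros(n)
    for comp in model.components:
        if comp.amp_ms2 == 0.0:
            continue
        if comp.freq_hz <= 0:
            raise ValueError("harmonic frequency must be positive for integration")
        omega = 2.0 * np.pi * comp.freq_hz
        s += (comp.amp_ms2 / omega**2) * np.cos(omega * t + comp.phase_rad + np.pi)
    return DisplacementSegment(values=s * 1000.0, fs=fs, t_start=t_start)


def depth_from_segment(segment: DisplacementSegment) -> float:
    """Peak-to-peak value of the average compression signal, mm."""
    if segment.values.size == 0:
        return 0.0
    return float(np.max(segment.values) - np.min(segment.values))


def rate_from_fundamental(f_cc: float) -> float:
    """Compression rate in cpm from the fundamental frequency in Hz."""
    if f_cc <= 0:
        raise ValueError("f_cc must be positive")
    return 60.0 * f_cc


def process_window(window: AnalysisWindow, config: RunConfig) -> WindowEstimate:
    """Classify one window and, if compressions are present, estimate
    depth/rate and reconstruct its displacement segment.

    The amount of work depends only on the window length and FFT size,
    never on episode length, so per-window latency is bounded.
    """
    det = classify_window(window, config.power_threshold)
    n = window.samples.size
    flat = DisplacementSegment(np.zeros(n), window.fs, window.t_start)
    if not det.is_compression:
        return WindowEstimate(window.index, window.t_start, det.power, False,
                              None, None, None, flat)
    spectrum = compute_spectrum(window, config.n_fft)
    try:
        f_cc = estimate_fundamental(spectrum, config.rate_band_cpm, config.subharmonic_ratio)
        model = extract_harmonics(
            spectrum, f_cc, config.n_harmonics, config.harmonic_tol_hz,
            config.noise_floor_ratio,
        )
    except NoSpectralPeakError as exc:
        logger.warning("window %d: %s; demoting to no-compression", window.index, exc)
        return WindowEstimate(window.index, window.t_start, det.power, False,
                              None, None, None, flat)
    segment = synthesize_displacement(model, n / window.fs, window.fs, window.t_start)
    return WindowEstimate(
        index=window.index,
        t_start=window.t_start,
        power=det.power,
        detected=True,
        depth_mm=depth_from_segment(segment),
        rate_cpm=rate_from_fundamental(f_cc),
        model=model,
        segment=segment,
    )


def process_episode(
    record: AccelerationRecord, config: RunConfig | None = None
) -> tuple[list[WindowEstimate], DisplacementSegment]:
    """Run the whole pipeline over an episode.

    Returns one estimate per non-overlapping window plus the concatenated
    displacement (no-compression windows contribute flat zero segments, so
    the reconstruction of a pause is a flat line).
    """
    config = config or RunConfig()
    windows = segment_windows(record, config.window_s)
    estimates = [process_window(w, config) for w in windows]
    if estimates:
        concat = np.concatenate([e.segment.values for e in estimates])
    else:
        concat = np.array([])
    return estimates, DisplacementSegment(concat, record.fs, record.start_time)


def oracle_double_integration(window: AnalysisWindow) -> DisplacementSegment:
    """Time-domain double integration of a noiseless periodic window (test oracle).

    Cumulative trapezoidal integration to velocity and then displacement,
    removing the mean at every stage.  For a window holding an integer
    number of sampled cycles the means are exactly the unknown integration
    constants, so the reconstruction is accurate to trapezoidal-rule error.
    Line fits are deliberately avoided: a periodic signal sampled over
    [0, T) has a non-zero least-squares slope (an edge effect), and
    subtracting it injects a cubic drift into the double integral.  Feed
    this oracle *raw* periodic samples, not detrended ones.  It is an
    independent reference for validating the spectral reconstruction; it is
    not part of the feedback path.
    """
    dt = 1.0 / window.fs
    x = window.samples - np.mean(window.samples)
    v = cumulative_trapezoid(x, dx=dt, initial=0.0)
    v = v - np.mean(v)
    s = cumulative_trapezoid(v, dx=dt, initial=0.0)
    s = s - np.mean(s)
    return DisplacementSegment(values=s * 1000.0, fs=window.fs, t_start=window.t_start)
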