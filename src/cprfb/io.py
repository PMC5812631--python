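"""Signal and result I/O, run configuration, and pipeline orchestration.

The on-disk interchange formats are deliberately plain:

* acceleration CSV — header ``time_s,accel_ms2``, one row per sample;
* displacement CSV — header ``time_s,disp_mm`` (negative values = downward
  chest displacement);
* per-window results CSV — ``index,t_start,power,detected,depth_mm,rate_cpm``
  with depth/rate left empty for windows without detected compressions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STANDARD_GRAVITY",
    "AccelerationRecord",
    "RunConfig",
    "SignalParseError",
    "read_signal_csv",
    "write_signal_csv",
    "write_displacement_csv",
    "write_results_csv",
    "read_results_csv",
    "process_episode_file",
]

logger = logging.getLogger("cprfb")

#: m/s² per g, ISO 80000-3 standard acceleration of free fall.
STANDARD_GRAVITY = 9.80665

#: Absolute tolerance (s) on sample-interval uniformity.
UNIFORMITY_TOL_S = 1e-6


class SignalParseError(ValueError):
    """Raised when an input signal file cannot be parsed."""


@dataclass(frozen=True)
class AccelerationRecord:
    """Uniformly sampled single-axis chest acceleration.

    Parameters
    ----------
    samples
        Acceleration values in m/s².
    fs
        Sampling rate in Hz (250 Hz for defibrillator-grade CPR pads).
    start_time
        Time offset of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the feedback pipeline.

    Attributes
    ----------
    window_s
        Analysis window length in seconds; the method issues one depth/rate
        estimate per window.
    power_threshold
        Compression-detection threshold on mean squared detrended
        acceleration, in (m/s²)².  The default equals the power of a
        sinusoidal 15 mm compression at 100 cpm, so shallow ~10 mm
        compressions fall below it while guideline-relevant depths pass.
    rate_band_cpm
        Physiologic search band for the compression rate.
    n_harmonics
        Number of spectral components kept, counting the fundamental.
    n_fft
        FFT length; zero-padding beyond the window refines peak
        interpolation.
    units_in
        Units of the input acceleration column: ``"ms2"`` or ``"g"``.
    subharmonic_ratio
        If the spectral magnitude at half the dominant in-band frequency is
        at least this fraction of the dominant magnitude, the half frequency
        is taken as the fundamental (guards against rate doubling).
    harmonic_tol_hz
        Search half-width around each expected harmonic frequency.
    noise_floor_ratio
        Harmonic peaks below this fraction of the fundamental's magnitude
        are treated as absent.
    """

    window_s: float = 2.0
    power_threshold: float = 0.34
    rate_band_cpm: tuple[float, float] = (50.0, 200.0)
    n_harmonics: int = 4
    n_fft: int = 8192
    units_in: str = "ms2"
    subharmonic_ratio: float = 0.5
    harmonic_tol_hz: float = 0.15
    noise_floor_ratio: float = 0.01

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        low, high = self.rate_band_cpm
        if not low < high:
            raise ValueError("rate_band_cpm must satisfy low < high")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be at least 1")
        if self.power_threshold < 0:
            raise ValueError("power_threshold must be non-negative")
        if self.units_in not in ("ms2", "g"):
            raise ValueError("units_in must be 'ms2' or 'g'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        if "rate_band_cpm" in data:
            data["rate_band_cpm"] = tuple(data["rate_band_cpm"])
        return cls(**data)

    def with_updates(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def read_signal_csv(path: str | Path, config: RunConfig | None = None) -> AccelerationRecord:
    """Read an acceleration CSV (``time_s,accel_ms2``) into a record.

    The sampling rate is inferred from the median time step; the time grid
    must be uniform to within 1 µs.  If ``config.units_in == "g"`` the
    acceleration column is converted to m/s².
    """
    config = config or RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SignalParseError(f"{path}: expected two columns (time_s, accel)")
    time = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    accel = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    bad = np.flatnonzero(time.isna().to_numpy() | accel.isna().to_numpy())
    if bad.size:
        # +2: one for the header row, one for 1-based line numbering
        raise SignalParseError(f"{path}: non-numeric value at line {bad[0] + 2}")
    t = time.to_numpy(dtype=float)
    a = accel.to_numpy(dtype=float)
    if t.size < 2:
        raise SignalParseError(f"{path}: need at least two samples to infer fs")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SignalParseError(f"{path}: time column must be strictly increasing")
    dt_med = float(np.median(dt))
    if np.max(np.abs(dt - dt_med)) > UNIFORMITY_TOL_S:
        raise SignalParseError(f"{path}: non-uniform sampling (tolerance {UNIFORMITY_TOL_S} s)")
    if config.units_in == "g":
        a = a * STANDARD_GRAVITY
    return AccelerationRecord(samples=a, fs=1.0 / dt_med, start_time=float(t[0]))


def write_signal_csv(path: str | Path, record: AccelerationRecord) -> None:
    df = pd.DataFrame({"time_s": record.times, "accel_ms2": record.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def write_displacement_csv(path: str | Path, times: np.ndarray, disp_mm: np.ndarray) -> None:
    df = pd.DataFrame({"time_s": times, "disp_mm": disp_mm})
    df.to_csv(path, index=False, float_format="%.6f")


def results_to_frame(estimates) -> pd.DataFrame:
    """Tabulate per-window estimates (depth/rate NaN when not detected)."""
    rows = []
    for est in estimates:
        rows.append(
            {
                "index": est.index,
                "t_start": est.t_start,
                "power": est.power,
                "detected": int(est.detected),
                "depth_mm": est.depth_mm if est.detected else np.nan,
                "rate_cpm": est.rate_cpm if est.detected else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["index", "t_start", "power", "detected", "depth_mm", "rate_cpm"]
    )


def write_results_csv(path: str | Path, estimates) -> pd.DataFrame:
    df = results_to_frame(estimates)
    df.to_csv(path, index=False, float_format="%.6f")
    return df


def read_results_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["index", "t_start", "power", "detected", "depth_mm", "rate_cpm"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SignalParseError(f"{path}: missing columns {missing}")
    return df


def process_episode_file(
    in_path: str | Path,
    out_path: str | Path,
    config: RunConfig | None = None,
    disp_path: str | Path | None = None,
) -> pd.DataFrame:
    """Run the full feedback pipeline on a signal file.

    Writes one row per non-overlapping window to ``out_path`` and, if
    ``disp_path`` is given, the concatenated reconstructed displacement at
    the input sampling rate.  Returns the results table.
    """
    from .reconstruction import process_episode  # deferred: avoids import cycle

    config = config or RunConfig()
    record = read_signal_csv(in_path, config)
    n_win = int(record.samples.size // round(config.window_s * record.fs))
    if n_win == 0:
        logger.warning("input shorter than one %.1f-s window; no output rows", config.window_s)
        df = results_to_frame([])
        df.to_csv(out_path, index=False)
        if disp_path is not None:
            write_displacement_csv(disp_path, np.array([]), np.array([]))
        return df
    estimates, concat = process_episode(record, config)
    df = write_results_csv(out_path, estimates)
    if disp_path is not None:
        times = record.start_time + np.arange(concat.values.size) / record.fs
        write_displacement_csv(disp_path, times, concat.values)
    return df
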