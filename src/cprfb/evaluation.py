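"""Evaluation machinery: gold-standard extraction, detector reliability and
accuracy statistics.

Given a trusted reference displacement (from a force-corrected device or the
simulator), compression events are picked as prominent troughs; per-window
gold-standard (GS) depth is the mean event depth and GS rate the inverse of
the mean inter-event interval.  The detector is scored by a window-level
confusion matrix (sensitivity, PPV); accuracy by signed/unsigned error
statistics over true-positive windows and Bland–Altman limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "ConfusionMatrix",
    "ErrorStats",
    "BlandAltman",
    "EvaluationReport",
    "detect_reference_events",
    "gold_window_values",
    "confusion_and_rates",
    "error_statistics",
    "bland_altman",
    "episode_inclusion",
    "evaluate_windows",
    "synthetic_benchmark",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity_pct(self) -> float | None:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else None

    @property
    def ppv_pct(self) -> float | None:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else None

    @property
    def fn_fraction_pct(self) -> float | None:
        denom = self.tp + self.fn
        return 100.0 * self.fn / denom if denom else None

    @property
    def fp_fraction_pct(self) -> float | None:
        denom = self.fp + self.tn
        return 100.0 * self.fp / denom if denom else None


@dataclass(frozen=True)
class ErrorStats:
    """Signed and unsigned error summary (percentiles by linear interpolation)."""

    mean: float
    sd: float  # population sd of the signed errors
    median: float
    p75: float
    p90: float
    p95: float
    p99: float
    min: float
    max: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mean_signed": self.mean,
            "sd_signed": self.sd,
            "median": self.median,
            "p75": self.p75,
            "p90": self.p90,
            "p95": self.p95,
            "p99": self.p99,
            "min": self.min,
            "max": self.max,
            "n": self.n,
        }


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float

    def to_dict(self) -> dict:
        return {"mean_diff": self.mean_diff, "loa_low": self.loa_low, "loa_high": self.loa_high}


def detect_reference_events(
    disp_mm: np.ndarray,
    fs: float,
    min_event_depth_mm: float = 7.0,
    refractory_s: float = 0.2,
) -> list[tuple[float, float]]:
    """Pick compression events (troughs) from a negative-down displacement.

    Events are local minima with prominence of at least
    ``min_event_depth_mm`` separated by at least ``refractory_s`` (a 300 cpm
    cap).  Event depth is the trough's prominence, i.e. its excursion
    relative to the surrounding recoil.  Returns (time_s, depth_mm) pairs.
    """
    disp_mm = np.asarray(disp_mm, dtype=float)
    if disp_mm.size < 3:
        return []
    idx, props = find_peaks(
        -disp_mm,
        prominence=min_event_depth_mm,
        distance=max(int(round(refractory_s * fs)), 1),
    )
    return [(float(i / fs), float(p)) for i, p in zip(idx, props["prominences"])]


def gold_window_values(
    events: list[tuple[float, float]], span: tuple[float, float]
) -> tuple[float | None, float | None]:
    """Per-window GS depth and rate from a time-ordered event list.

    GS depth averages the depths of events whose trough lies in the span
    (absent without events); GS rate is 60 over the mean interval between
    consecutive in-span events (absent with fewer than two events).
    """
    t0, t1 = span
    inside = [(t, d) for t, d in events if t0 <= t < t1]
    if not inside:
        return None, None
    gs_depth = float(np.mean([d for _, d in inside]))
    if len(inside) < 2:
        return gs_depth, None
    times = np.array([t for t, _ in inside])
    gs_rate = 60.0 / float(np.mean(np.diff(times)))
    return gs_depth, gs_rate


def confusion_and_rates(
    predicted: np.ndarray, gold: np.ndarray
) -> tuple[ConfusionMatrix, float | None, float | None]:
    """Window-level confusion matrix plus sensitivity and PPV in percent.

    Undefined ratios (zero denominator) are returned as None, never as 0.
    """
    predicted = np.asarray(predicted, dtype=bool)
    gold = np.asarray(gold, dtype=bool)
    if predicted.shape != gold.shape:
        raise ValueError("predicted and gold label sequences must have equal length")
    cm = ConfusionMatrix(
        tp=int(np.sum(predicted & gold)),
        fp=int(np.sum(predicted & ~gold)),
        fn=int(np.sum(~predicted & gold)),
        tn=int(np.sum(~predicted & ~gold)),
    )
    return cm, cm.sensitivity_pct, cm.ppv_pct


def error_statistics(pairs: list[tuple[float, float]]) -> ErrorStats:
    """Signed (mean, sd) and unsigned percentile statistics of estimate − GS."""
    if not pairs:
        raise ValueError("error_statistics requires at least one (estimate, GS) pair")
    signed = np.array([est - gs for est, gs in pairs], dtype=float)
    unsigned = np.abs(signed)
    med, p75, p90, p95, p99 = np.percentile(unsigned, [50, 75, 90, 95, 99])
    return ErrorStats(
        mean=float(np.mean(signed)),
        sd=float(np.std(signed)),
        median=float(med),
        p75=float(p75),
        p90=float(p90),
        p95=float(p95),
        p99=float(p99),
        min=float(np.min(unsigned)),
        max=float(np.max(unsigned)),
        n=signed.size,
    )


def bland_altman(pairs: list[tuple[float, float]]) -> BlandAltman:
    """Mean difference and 95% limits of agreement (mean ± 1.96·sd, population sd)."""
    if len(pairs) < 2:
        raise ValueError("bland_altman requires at least two pairs")
    d = np.array([est - gs for est, gs in pairs], dtype=float)
    mean = float(np.mean(d))
    sd = float(np.std(d))
    return BlandAltman(mean_diff=mean, loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd)


def episode_inclusion(duration_s: float, n_compressions: int, mean_depth_mm: float) -> bool:
    """Episode quality filter: ≥20 min, >1500 compressions, mean depth ≥30 mm."""
    if min(duration_s, n_compressions, mean_depth_mm) < 0:
        raise ValueError("inputs must be non-negative")
    return duration_s >= 1200.0 and n_compressions > 1500 and mean_depth_mm >= 30.0


@dataclass(frozen=True)
class EvaluationReport:
    confusion: ConfusionMatrix
    sensitivity_pct: float | None
    ppv_pct: float | None
    depth_errors: ErrorStats | None
    rate_errors: ErrorStats | None
    depth_bland_altman: BlandAltman | None
    rate_bland_altman: BlandAltman | None

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
                "total": self.confusion.total,
            },
            "sensitivity_pct": self.sensitivity_pct,
            "ppv_pct": self.ppv_pct,
            "depth_errors_mm": self.depth_errors.to_dict() if self.depth_errors else None,
            "rate_errors_cpm": self.rate_errors.to_dict() if self.rate_errors else None,
            "depth_bland_altman_mm": (
                self.depth_bland_altman.to_dict() if self.depth_bland_altman else None
            ),
            "rate_bland_altman_cpm": (
                self.rate_bland_altman.to_dict() if self.rate_bland_altman else None
            ),
        }


def evaluate_windows(
    predicted: list[tuple[bool, float | None, float | None]],
    gold: list[tuple[bool, float | None, float | None]],
) -> EvaluationReport:
    """Score aligned per-window (detected, depth, rate) against gold labels.

    Error and agreement statistics use true-positive windows only, and a
    window enters the depth (rate) pairing only when both the estimate and
    the GS value exist — windows whose GS rate is undefined (fewer than two
    reference events) are excluded from rate errors.
    """
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold sequences must have equal length")
    pred_labels = np.array([p[0] for p in predicted], dtype=bool)
    gold_labels = np.array([g[0] for g in gold], dtype=bool)
    cm, sens, ppv = confusion_and_rates(pred_labels, gold_labels)

    depth_pairs, rate_pairs = [], []
    for (p_det, p_depth, p_rate), (g_lab, g_depth, g_rate) in zip(predicted, gold):
        if not (p_det and g_lab):
            continue
        if p_depth is not None and g_depth is not None:
            depth_pairs.append((p_depth, g_depth))
        if p_rate is not None and g_rate is not None:
            rate_pairs.append((p_rate, g_rate))

    return EvaluationReport(
        confusion=cm,
        sensitivity_pct=sens,
        ppv_pct=ppv,
        depth_errors=error_statistics(depth_pairs) if depth_pairs else None,
        rate_errors=error_statistics(rate_pairs) if rate_pairs else None,
        depth_bland_altman=bland_altman(depth_pairs) if len(depth_pairs) >= 2 else None,
        rate_bland_altman=bland_altman(rate_pairs) if len(rate_pairs) >= 2 else None,
    )


def synthetic_benchmark(
    n_episodes: int = 30,
    episode_s: float = 120.0,
    seed: int = 0,
    noise_sd_ms2: float = 0.15,
    config=None,
) -> dict:
    """End-to-end benchmark on seeded synthetic episodes.

    Generates ``n_episodes`` OHCA-style episodes, runs the feedback pipeline
    on each, pools the per-window results against the simulator's ground
    truth and returns the aggregate evaluation plus GS summary statistics.
    Windows straddling a compression-series onset/offset have no clean
    class under interval-based annotation and are excluded from scoring
    (the simulator analog of manually annotated C/NC intervals).
    """
    from .io import RunConfig
    from .reconstruction import process_episode
    from .synthetic import (
        compression_intervals,
        generate_episode,
        paper_like_scenario,
        window_ambiguity_mask,
    )

    config = config or RunConfig()
    predicted, gold = [], []
    gs_depths, gs_rates = [], []
    n_excluded = 0
    for i in range(n_episodes):
        scenario = paper_like_scenario(
            duration_s=episode_s, seed=seed + i, noise_sd_ms2=noise_sd_ms2
        )
        record, _, annotations = generate_episode(scenario, window_s=config.window_s)
        estimates, _ = process_episode(record, config)
        clean = window_ambiguity_mask(
            compression_intervals(scenario), len(annotations), config.window_s
        )
        n_excluded += int(np.sum(~clean))
        for est, ann in zip(estimates, annotations):
            if not clean[ann.index]:
                continue
            predicted.append((est.detected, est.depth_mm, est.rate_cpm))
            gold.append((ann.is_compression, ann.gs_depth_mm, ann.gs_rate_cpm))
            if ann.is_compression and ann.gs_depth_mm is not None:
                gs_depths.append(ann.gs_depth_mm)
            if ann.is_compression and ann.gs_rate_cpm is not None:
                gs_rates.append(ann.gs_rate_cpm)
    report = evaluate_windows(predicted, gold)
    return {
        "report": report,
        "n_windows": len(gold),
        "n_excluded_transition_windows": n_excluded,
        "n_compression_windows": int(sum(g[0] for g in gold)),
        "gs_depth_median_mm": float(np.median(gs_depths)) if gs_depths else None,
        "gs_rate_median_cpm": float(np.median(gs_rates)) if gs_rates else None,
    }
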