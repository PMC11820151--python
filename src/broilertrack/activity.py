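"""Accelerometer-based active/inactive classification.

A motionless accelerometer reads the gravity vector, so the Euclidean
magnitude of the three axes is 1 g regardless of mounting orientation.
Motion perturbs the magnitude away from its baseline; thresholding the
absolute deviation (default 0.05 g) classifies samples as active, and a
1-second window counts as active if it contains at least one active
sample. Active fractions are then aggregated over reporting intervals
(default 4 h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ImuTrace

__all__ = [
    "ActivityConfig",
    "ActivitySummary",
    "magnitude",
    "activity_mask",
    "active_fraction",
    "threshold_sweep",
    "axis_summaries",
]

BASELINE_MODES = ("gravity_1g", "per_tag_mean")


@dataclass(frozen=True)
class ActivityConfig:
    """Classification parameters.

    threshold : g
        Deviation that a sample must *exceed* (strictly) to count as
        active. Default 0.05 g.
    baseline_mode
        ``gravity_1g`` uses a fixed 1 g baseline; ``per_tag_mean`` uses
        the tag's whole-trace mean magnitude (default — absorbs any
        constant calibration offset).
    window_s
        Window for the at-least-one-active-sample rule (default 1 s).
    aggregation_s
        Reporting interval for active fractions (default 4 h); must be a
        multiple of the window.
    """

    threshold: float = 0.05
    baseline_mode: str = "per_tag_mean"
    window_s: float = 1.0
    aggregation_s: float = 14400.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.baseline_mode not in BASELINE_MODES:
            raise ValueError(f"baseline_mode must be one of {BASELINE_MODES}")
        if self.window_s <= 0 or self.aggregation_s <= 0:
            raise ValueError("window_s and aggregation_s must be > 0")
        ratio = self.aggregation_s / self.window_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("window_s must divide aggregation_s")


@dataclass(frozen=True)
class ActivitySummary:
    """Per-interval and overall active fractions for one tag."""

    tag_id: object
    intervals: pd.DataFrame  # columns: t_start, n_windows, active_fraction
    overall_active_fraction: float


def magnitude(trace: ImuTrace) -> np.ndarray:
    """Per-sample Euclidean magnitude sqrt(ax^2 + ay^2 + az^2) in g."""
    s = trace.samples
    if not np.all(np.isfinite(s)):
        raise ValueError("IMU samples must be finite")
    return np.sqrt(np.einsum("ij,ij->i", s, s))


def _baseline(m: np.ndarray, cfg: ActivityConfig) -> float:
    if cfg.baseline_mode == "gravity_1g":
        return 1.0
    if len(m) == 0:
        raise ValueError("per_tag_mean baseline needs at least one sample")
    return float(m.mean())


def activity_mask(m: np.ndarray, cfg: ActivityConfig) -> np.ndarray:
    """Per-sample active flags: |m - baseline| strictly above threshold."""
    base = _baseline(np.asarray(m, dtype=float), cfg)
    return np.abs(m - base) > cfg.threshold


def active_fraction(mask: np.ndarray, cfg: ActivityConfig, rate_hz: float,
                    tag_id: object = None, t_start: float = 0.0) -> ActivitySummary:
    """Windowed active fractions from a per-sample mask.

    A window is active iff at least one of its samples is active. Windows
    are non-overlapping, aligned to the trace start; a partial trailing
    window is dropped. The overall fraction is the duration-weighted mean
    over reporting intervals, i.e. active windows / total windows.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty activity mask")
    spw = int(round(cfg.window_s * rate_hz))
    if spw < 1 or mask.size < spw:
        raise ValueError("trace must span at least one window")
    n_windows = mask.size // spw
    win_active = mask[: n_windows * spw].reshape(n_windows, spw).any(axis=1)

    wpi = int(round(cfg.aggregation_s / cfg.window_s))
    starts, fracs, counts = [], [], []
    for i in range(0, n_windows, wpi):
        chunk = win_active[i: i + wpi]
        starts.append(t_start + i * cfg.window_s)
        counts.append(chunk.size)
        fracs.append(chunk.mean())
    intervals = pd.DataFrame({"t_start": starts, "n_windows": counts,
                              "active_fraction": fracs})
    overall = float(win_active.mean())
    return ActivitySummary(tag_id, intervals, overall)


def threshold_sweep(m: np.ndarray, cfg: ActivityConfig,
                    thresholds) -> pd.DataFrame:
    """Per-sample active proportion for each candidate threshold.

    The proportion is the survival function of the absolute deviation
    distribution evaluated at each threshold, hence monotone
    non-increasing.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size < 2:
        raise ValueError("threshold grid needs at least 2 points")
    dev = np.sort(np.abs(np.asarray(m, dtype=float) - _baseline(m, cfg)))
    # count of deviations strictly greater than each threshold
    above = dev.size - np.searchsorted(dev, thresholds, side="right")
    return pd.DataFrame({"threshold": thresholds,
                         "active_proportion": above / dev.size})


def axis_summaries(trace: ImuTrace) -> pd.DataFrame:
    """Distribution statistics per axis and for the magnitude.

    Per-axis statistics shift with the mounting orientation of the sensor
    on the bird; magnitude statistics do not.
    """
    if len(trace.t) < 2:
        raise ValueError("need at least 2 samples")
    cols = {"x": trace.samples[:, 0], "y": trace.samples[:, 1],
            "z": trace.samples[:, 2], "magnitude": magnitude(trace)}
    rows = []
    for name, v in cols.items():
        q25, q50, q75 = np.percentile(v, [25, 50, 75])
        rows.append({"channel": name, "mean": v.mean(), "sd": v.std(ddof=1),
                     "min": v.min(), "q25": q25, "median": q50, "q75": q75,
                     "max": v.max()})
    return pd.DataFrame(rows)
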