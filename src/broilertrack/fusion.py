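"""UWB x IMU synergy: location-conditioned activity, movement correlation,
motion-triggered duty cycling, and uplink bandwidth accounting.

The two sensors are complementary: UWB reports where a bird is (and how
far it moved), the accelerometer reports how vigorously it moves even
when stationary. Correlating windowed IMU features against windowed UWB
travel distance shows whether cheap IMU data can proxy for movement; a
motion trigger that wakes the UWB radio only when the IMU feature is high
exploits the birds' long resting bouts to save transmissions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .activity import magnitude
from .layout import PenLayout
from .simulate import ImuTrace
from .uwb import FixSeries

__all__ = [
    "FusionConfig",
    "TriggerConfig",
    "ConfusionReport",
    "resample_features",
    "movement_correlation",
    "location_activity_map",
    "motion_trigger_eval",
    "trigger_windows",
    "duty_cycle_savings",
    "uplink_bandwidth",
]

CHANNELS = ("x", "y", "z", "magnitude")
STATS = ("mean", "std")


@dataclass(frozen=True)
class FusionConfig:
    """Resampling grid for the movement-correlation analysis.

    IMU samples are always pre-aggregated to 1 s means per channel before
    the window statistic (mean or std) is taken; UWB contributes the
    Euclidean distance traveled within each window.
    """

    resample_windows_s: tuple[float, ...] = (16.0, 60.0, 300.0, 600.0)
    imu_stats: tuple[str, ...] = STATS
    imu_channels: tuple[str, ...] = CHANNELS
    pre_aggregation_s: float = 1.0

    def __post_init__(self) -> None:
        if any(w < self.pre_aggregation_s for w in self.resample_windows_s):
            raise ValueError("resample windows must be >= pre_aggregation_s")
        if any(s not in STATS for s in self.imu_stats):
            raise ValueError(f"imu_stats must be from {STATS}")
        if any(c not in CHANNELS for c in self.imu_channels):
            raise ValueError(f"imu_channels must be from {CHANNELS}")


@dataclass(frozen=True)
class TriggerConfig:
    """Motion-trigger evaluation parameters.

    The IMU feature is the sum over the window of per-second standard
    deviations of the acceleration magnitude; a window truly contains
    movement when the UWB distance meets ``distance_threshold_m``
    (default: 5 m per half hour).
    """

    window_s: float = 1800.0
    distance_threshold_m: float = 5.0

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if self.distance_threshold_m <= 0:
            raise ValueError("distance_threshold_m must be > 0")


@dataclass(frozen=True)
class ConfusionReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def false_negative_rate(self) -> float:
        return 1.0 - self.sensitivity

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / n if n else float("nan")


def _imu_1s_table(imu: ImuTrace, pre_s: float = 1.0) -> pd.DataFrame:
    """Per-second channel means (x, y, z, magnitude) and magnitude std."""
    m = magnitude(imu)
    t0 = imu.t[0]
    sec = np.floor((imu.t - t0) / pre_s).astype(np.int64)
    df = pd.DataFrame({"sec": sec, "x": imu.samples[:, 0], "y": imu.samples[:, 1],
                       "z": imu.samples[:, 2], "magnitude": m})
    g = df.groupby("sec")
    out = g.mean()
    out["magnitude_std"] = g["magnitude"].std(ddof=0).fillna(0.0)
    out = out.reset_index()
    out["t"] = t0 + out["sec"] * pre_s
    return out


def _window_distances(fixes: FixSeries, t_start: float, window_s: float,
                      n_windows: int) -> np.ndarray:
    """Euclidean distance traveled per window (pair assigned to the
    earlier fix's window)."""
    dist = np.zeros(n_windows)
    if len(fixes) < 2:
        return dist
    steps = np.linalg.norm(np.diff(fixes.xy, axis=0), axis=1)
    idx = np.floor((fixes.t[:-1] - t_start) / window_s).astype(int)
    ok = (idx >= 0) & (idx < n_windows)
    np.add.at(dist, idx[ok], steps[ok])
    return dist


def resample_features(imu: ImuTrace, fixes: FixSeries,
                      cfg: FusionConfig = FusionConfig()) -> pd.DataFrame:
    """Paired IMU/UWB features on each resampling window.

    Returns a tidy table with one row per (window length, window start,
    channel, stat): ``imu_feature`` is the window mean or std of the 1-s
    channel means, ``uwb_distance_m`` the distance traveled in that
    window. Windows are anchored at the first common timestamp and
    non-overlapping; only windows fully inside the common span are kept.
    """
    t_lo = max(imu.t[0], fixes.t[0] if len(fixes) else imu.t[0])
    t_hi = min(imu.t[-1], fixes.t[-1] if len(fixes) else imu.t[-1])
    if t_hi <= t_lo:
        raise ValueError("IMU and UWB time ranges do not overlap")
    table_1s = _imu_1s_table(imu, cfg.pre_aggregation_s)
    table_1s = table_1s[(table_1s["t"] >= t_lo) & (table_1s["t"] < t_hi)]
    rows = []
    for w in cfg.resample_windows_s:
        n_win = int(np.floor((t_hi - t_lo) / w))
        if n_win < 2:
            continue
        win = np.floor((table_1s["t"].to_numpy() - t_lo) / w).astype(int)
        keep = win < n_win
        sub = table_1s[keep].copy()
        sub["win"] = win[keep]
        dists = _window_distances(fixes, t_lo, w, n_win)
        g = sub.groupby("win")
        for ch in cfg.imu_channels:
            agg = {"mean": g[ch].mean(), "std": g[ch].std(ddof=0)}
            for st in cfg.imu_stats:
                feat = agg[st]
                for win_i, val in feat.items():
                    rows.append({"window_s": w, "t_start": t_lo + win_i * w,
                                 "channel": ch, "stat": st,
                                 "imu_feature": float(val),
                                 "uwb_distance_m": float(dists[win_i])})
    return pd.DataFrame(rows)


def movement_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between IMU feature and UWB distance per
    (window, channel, stat) configuration, sorted by |r| descending.

    Configurations with fewer than 3 rows or a zero-variance feature are
    reported with ``r`` NaN and a note.
    """
    out = []
    for (w, ch, st), sub in table.groupby(["window_s", "channel", "stat"]):
        sub = sub.dropna(subset=["imu_feature", "uwb_distance_m"])
        note = ""
        if len(sub) < 3:
            r, note = np.nan, "fewer than 3 windows"
        elif sub["imu_feature"].std() == 0 or sub["uwb_distance_m"].std() == 0:
            r, note = np.nan, "zero-variance feature"
        else:
            r = float(stats.pearsonr(sub["imu_feature"], sub["uwb_distance_m"])[0])
        out.append({"window_s": w, "channel": ch, "stat": st, "r": r,
                    "n": len(sub), "note": note})
    df = pd.DataFrame(out)
    return df.sort_values("r", key=lambda s: s.abs(), ascending=False,
                          na_position="last").reset_index(drop=True)


def location_activity_map(fixes: FixSeries, imu: ImuTrace, layout: PenLayout,
                          stat: str = "std", bin_size: float = 0.15,
                          uwb_period_s: float = 32.0):
    """Grid of an IMU activity statistic by pen location.

    Each 1-s magnitude aggregate is assigned to the grid cell of the
    nearest-in-time fix (within half a UWB period); per-cell ``max``,
    ``std`` or ``mean`` of the 1-s magnitude std summarizes local
    activity. Cells with no data are NaN.
    """
    if stat not in ("max", "std", "mean"):
        raise ValueError("stat must be one of max, std, mean")
    if len(fixes) == 0 or imu.t[0] > fixes.t[-1] or imu.t[-1] < fixes.t[0]:
        raise ValueError("IMU and fix time ranges do not overlap")
    table_1s = _imu_1s_table(imu)
    ts = table_1s["t"].to_numpy()
    k = np.searchsorted(fixes.t, ts)
    k = np.clip(k, 1, len(fixes.t) - 1)
    left, right = fixes.t[k - 1], fixes.t[k]
    nearest = np.where(ts - left <= right - ts, k - 1, k)
    gap = np.abs(fixes.t[nearest] - ts)
    keep = gap <= uwb_period_s / 2.0
    xy = layout.clip(fixes.xy[nearest[keep]])
    vals = table_1s["magnitude_std"].to_numpy()[keep]

    nx = max(1, int(np.ceil(layout.width / bin_size)))
    ny = max(1, int(np.ceil(layout.height / bin_size)))
    i = np.minimum((xy[:, 0] / bin_size).astype(int), nx - 1)
    j = np.minimum((xy[:, 1] / bin_size).astype(int), ny - 1)
    df = pd.DataFrame({"cell": i * ny + j, "v": vals})
    agg = getattr(df.groupby("cell")["v"], stat)()
    grid = np.full((nx, ny), np.nan)
    cells = agg.index.to_numpy()
    grid[cells // ny, cells % ny] = agg.to_numpy()
    return grid


def trigger_windows(imu: ImuTrace, fixes: FixSeries,
                    cfg: TriggerConfig = TriggerConfig()) -> pd.DataFrame:
    """Per-window IMU feature and UWB distance for the motion trigger.

    Feature: sum over the window of per-second magnitude standard
    deviations. Truth: the window is a movement window iff the UWB
    distance meets the distance threshold.
    """
    t_lo = max(imu.t[0], fixes.t[0] if len(fixes) else imu.t[0])
    t_hi = min(imu.t[-1], fixes.t[-1] if len(fixes) else imu.t[-1])
    n_win = int(np.floor((t_hi - t_lo) / cfg.window_s))
    if n_win < 4:
        raise ValueError("need at least 4 full windows for trigger evaluation")
    table_1s = _imu_1s_table(imu)
    ts = table_1s["t"].to_numpy()
    win = np.floor((ts - t_lo) / cfg.window_s).astype(int)
    keep = (win >= 0) & (win < n_win)
    feat = np.zeros(n_win)
    np.add.at(feat, win[keep], table_1s["magnitude_std"].to_numpy()[keep])
    dist = _window_distances(fixes, t_lo, cfg.window_s, n_win)
    return pd.DataFrame({"t_start": t_lo + np.arange(n_win) * cfg.window_s,
                         "imu_feature": feat, "uwb_distance_m": dist,
                         "moved": dist >= cfg.distance_threshold_m})


def motion_trigger_eval(imu: ImuTrace, fixes: FixSeries,
                        cfg: TriggerConfig = TriggerConfig(),
                        imu_threshold: float | None = None,
                        threshold_grid=None):
    """Evaluate the IMU-based wake-up trigger against UWB ground truth.

    With a single ``imu_threshold`` returns a :class:`ConfusionReport`;
    with a ``threshold_grid`` (or neither, in which case a grid spanning
    the feature range is used) returns a ROC-style sweep table.
    """
    wins = trigger_windows(imu, fixes, cfg)
    truth = wins["moved"].to_numpy()
    if truth.all() or not truth.any():
        warnings.warn("all windows belong to one class; trigger metrics degenerate",
                      stacklevel=2)
    feat = wins["imu_feature"].to_numpy()

    def confusion(thr: float) -> ConfusionReport:
        pred = feat >= thr
        return ConfusionReport(tp=int((pred & truth).sum()),
                               fp=int((pred & ~truth).sum()),
                               tn=int((~pred & ~truth).sum()),
                               fn=int((~pred & truth).sum()))

    if imu_threshold is not None:
        return confusion(float(imu_threshold))
    if threshold_grid is None:
        threshold_grid = np.unique(np.quantile(feat, np.linspace(0, 1, 101)))
    rows = []
    for thr in np.asarray(threshold_grid, dtype=float):
        c = confusion(thr)
        rows.append({"imu_threshold": thr, "tp": c.tp, "fp": c.fp, "tn": c.tn,
                     "fn": c.fn, "sensitivity": c.sensitivity,
                     "specificity": c.specificity,
                     "false_negative_rate": c.false_negative_rate})
    return pd.DataFrame(rows)


def duty_cycle_savings(trigger_mask, t0: float, window_s: float,
                       fixes: FixSeries) -> float:
    """Fraction of UWB fixes that the sleep policy would suppress.

    ``trigger_mask[i]`` says whether the trigger predicts movement during
    window ``[t0 + i*window_s, t0 + (i+1)*window_s)``; a fix is suppressed
    when it falls in a predicted-negative window. The mask must cover the
    whole fix timeline.
    """
    trigger_mask = np.asarray(trigger_mask, dtype=bool)
    if len(fixes) == 0:
        raise ValueError("no fixes on the trigger timeline")
    idx = np.floor((fixes.t - t0) / window_s).astype(int)
    if idx.min() < 0 or idx.max() >= trigger_mask.size:
        raise ValueError("trigger mask does not cover the fix timeline")
    return float((~trigger_mask[idx]).mean())


def uplink_bandwidth(rate_hz: float, n_axes: int, bits_per_value: int) -> float:
    """Uplink throughput in bytes per second per animal.

    A 20 Hz tri-axial accelerometer at 8 bits per value needs
    20 * 3 * 8 / 8 = 60 bytes/s per bird.
    """
    if rate_hz < 0 or n_axes < 0 or bits_per_value < 0:
        raise ValueError("bandwidth inputs must be >= 0")
    return rate_hz * n_axes * bits_per_value / 8.0
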