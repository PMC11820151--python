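"""IMU x UWB fusion: feature pairing, correlation grid, motion trigger."""

import numpy as np
import pandas as pd
import pytest

from broilertrack.fusion import (FusionConfig, TriggerConfig,
                                 duty_cycle_savings, location_activity_map,
                                 motion_trigger_eval, movement_correlation,
                                 resample_features, trigger_windows,
                                 uplink_bandwidth)
from broilertrack.simulate import ImuTrace
from broilertrack.uwb import FixSeries


def constant_imu(n_sec, rate=20.0, value=(0.0, 0.0, 1.0), tag="c"):
    n = int(n_sec * rate)
    return ImuTrace(tag, rate, np.arange(n) / rate, np.tile(value, (n, 1)))


def coupled_data(n_sec=21600, seed=0, rate=20.0, period=32.0):
    """IMU bursts and UWB displacement driven by one on/off schedule."""
    rng = np.random.default_rng(seed)
    n_sec = int(n_sec)
    # long rest bouts (mean ~45 min) so that whole half-hour windows of
    # stillness exist; activity bouts average ~7 min
    active = np.zeros(n_sec, dtype=bool)
    t, state = 0, False
    while t < n_sec:
        state = not state
        bout = int(rng.exponential(420 if state else 2700)) + 30
        active[t: t + bout] = state
        t += bout
    # IMU: gravity + burst noise while active
    n = int(n_sec * rate)
    samples = np.tile([0.0, 0.0, 1.0], (n, 1)) + rng.normal(0, 0.01, (n, 3))
    mask = np.repeat(active, int(rate))
    samples[mask] += rng.normal(0, 0.25, (int(mask.sum()), 3))
    imu = ImuTrace("cpl", rate, np.arange(n) / rate, samples)
    # UWB: random walk while active, still otherwise, small noise
    speed = np.where(active, 0.25, 0.0)
    heading = np.cumsum(rng.normal(0, 0.3, n_sec))
    xy = np.cumsum(np.column_stack([speed * np.cos(heading),
                                    speed * np.sin(heading)]), axis=0)
    ft = np.arange(0.0, n_sec, period)
    fxy = xy[ft.astype(int)] + rng.normal(0, 0.02, (len(ft), 2))
    return imu, FixSeries("cpl", ft, fxy), active


class TestResampleFeatures:
    def test_constant_imu_static_tag_all_flat(self):
        imu = constant_imu(600)
        fixes = FixSeries("c", np.arange(0.0, 600.0, 32.0), np.tile([1.0, 1.0], (19, 1)))
        tbl = resample_features(imu, fixes, FusionConfig(resample_windows_s=(60.0,)))
        assert (tbl["uwb_distance_m"] == 0).all()
        stds = tbl[tbl["stat"] == "std"]["imu_feature"]
        assert np.allclose(stds, 0.0)

    def test_whole_trace_window_equals_global_stats(self):
        rng = np.random.default_rng(1)
        n_sec = 1200
        imu = ImuTrace("w", 20.0, np.arange(n_sec * 20) / 20.0,
                       rng.normal(0, 0.1, (n_sec * 20, 3)) + [0, 0, 1])
        fixes = FixSeries("w", np.arange(0.0, n_sec, 32.0),
                          rng.uniform(0, 3, (len(np.arange(0.0, n_sec, 32.0)), 2)))
        w = 590.0
        tbl = resample_features(imu, fixes, FusionConfig(resample_windows_s=(w,)))
        row = tbl[(tbl.channel == "z") & (tbl.stat == "mean")]
        assert len(row) == 2  # floor(overlap / window) rows
        # window mean of 1-s z-means equals the z mean over that window
        z0 = imu.samples[: int(w) * 20, 2].mean()
        assert row["imu_feature"].iloc[0] == pytest.approx(z0, abs=1e-6)

    def test_row_count_is_floor_overlap_over_window(self):
        imu, fixes, _ = coupled_data(n_sec=3600, seed=3)
        cfg = FusionConfig()
        tbl = resample_features(imu, fixes, cfg)
        overlap = min(imu.t[-1], fixes.t[-1]) - max(imu.t[0], fixes.t[0])
        for w in cfg.resample_windows_s:
            rows = tbl[(tbl.window_s == w) & (tbl.channel == "x") & (tbl.stat == "std")]
            assert len(rows) == int(np.floor(overlap / w))

    def test_disjoint_ranges_rejected(self):
        imu = constant_imu(100)
        fixes = FixSeries("d", np.array([5000.0, 5032.0]), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="overlap"):
            resample_features(imu, fixes)

    def test_matches_brute_force_recomputation(self):
        imu, fixes, _ = coupled_data(n_sec=1800, seed=4)
        w = 300.0
        tbl = resample_features(imu, fixes, FusionConfig(resample_windows_s=(w,)))
        sub = tbl[(tbl.channel == "magnitude") & (tbl.stat == "std")].reset_index()
        m = np.linalg.norm(imu.samples, axis=1)
        sec_means = m.reshape(-1, 20).mean(axis=1)
        for k in range(len(sub)):
            lo = int(k * w)
            expect = sec_means[lo: lo + int(w)].std(ddof=0)
            assert sub["imu_feature"][k] == pytest.approx(expect, abs=1e-9)
        # UWB distances: brute-force per window
        steps = np.linalg.norm(np.diff(fixes.xy, axis=0), axis=1)
        wins = np.floor(fixes.t[:-1] / w).astype(int)
        for k in range(len(sub)):
            assert sub["uwb_distance_m"][k] == pytest.approx(steps[wins == k].sum())


class TestMovementCorrelation:
    def test_feature_proportional_to_speed_high_r(self):
        rng = np.random.default_rng(5)
        n = 200
        dist = rng.uniform(0, 10, n)
        tbl = pd.DataFrame({"window_s": 300.0, "t_start": np.arange(n) * 300.0,
                            "channel": "magnitude", "stat": "std",
                            "imu_feature": dist * 0.01 + rng.normal(0, 0.001, n),
                            "uwb_distance_m": dist})
        r = movement_correlation(tbl)["r"].iloc[0]
        assert r > 0.95

    def test_independent_streams_near_zero(self):
        rng = np.random.default_rng(6)
        n = 720
        tbl = pd.DataFrame({"window_s": 60.0, "t_start": np.arange(n) * 60.0,
                            "channel": "x", "stat": "mean",
                            "imu_feature": rng.normal(size=n),
                            "uwb_distance_m": rng.normal(size=n)})
        assert abs(movement_correlation(tbl)["r"].iloc[0]) < 0.1

    def test_zero_variance_reported_not_raised(self):
        tbl = pd.DataFrame({"window_s": 60.0, "t_start": np.arange(5) * 60.0,
                            "channel": "z", "stat": "mean",
                            "imu_feature": np.ones(5),
                            "uwb_distance_m": np.arange(5.0)})
        out = movement_correlation(tbl)
        assert np.isnan(out["r"].iloc[0])
        assert "zero-variance" in out["note"].iloc[0]

    def test_affine_rescaling_invariance(self):
        imu, fixes, _ = coupled_data(n_sec=3600, seed=7)
        tbl = resample_features(imu, fixes, FusionConfig(resample_windows_s=(300.0,)))
        base = movement_correlation(tbl)
        tbl2 = tbl.copy()
        tbl2["imu_feature"] = 3.5 * tbl2["imu_feature"] + 0.2
        again = movement_correlation(tbl2)
        pd.testing.assert_frame_equal(base.drop(columns="note"),
                                      again.drop(columns="note"),
                                      check_exact=False, rtol=1e-9)

    def test_long_std_windows_beat_short_windows(self):
        imu, fixes, _ = coupled_data(n_sec=21600, seed=8)
        corr = movement_correlation(resample_features(imu, fixes, FusionConfig()))
        best_300_std = corr.query("window_s == 300 and stat == 'std'")["r"].max()
        best_16 = corr.query("window_s == 16")["r"].abs().max()
        assert best_300_std > best_16


class TestLocationActivityMap:
    def test_feeder_burst_cells_have_highest_std(self):
        rng = np.random.default_rng(9)
        n_sec = 3600
        # bird alternates: near feeder (bursting) and corner (still)
        at_feeder = (np.arange(n_sec) // 300) % 2 == 0
        pos = np.where(at_feeder[:, None], [1.4, 1.5], [0.3, 0.3])
        ft = np.arange(0.0, n_sec, 32.0)
        fixes = FixSeries("f", ft, pos[ft.astype(int)].astype(float))
        n = n_sec * 20
        samples = np.tile([0.0, 0.0, 1.0], (n, 1)) + rng.normal(0, 0.005, (n, 3))
        mask = np.repeat(at_feeder, 20)
        samples[mask] += rng.normal(0, 0.3, (int(mask.sum()), 3))
        imu = ImuTrace("f", 20.0, np.arange(n) / 20.0, samples)
        from broilertrack.layout import PenLayout
        pen = PenLayout.square_pen()
        grid = location_activity_map(fixes, imu, pen, stat="std", bin_size=0.5)
        finite = np.nan_to_num(grid, nan=-1)
        peak = np.unravel_index(np.argmax(finite), grid.shape)
        # feeder sits at (1.4, 1.5) -> cell (2, 3) at 0.5 m bins
        assert peak == (2, 3)

    def test_uniform_activity_flat_map(self):
        rng = np.random.default_rng(10)
        n_sec = 7200
        ft = np.arange(0.0, n_sec, 32.0)
        fixes = FixSeries("u", ft, rng.uniform(0.5, 2.5, (len(ft), 2)))
        n = n_sec * 20
        imu = ImuTrace("u", 20.0, np.arange(n) / 20.0,
                       np.tile([0, 0, 1.0], (n, 1)) + rng.normal(0, 0.1, (n, 3)))
        from broilertrack.layout import PenLayout
        grid = location_activity_map(fixes, imu, PenLayout.square_pen(),
                                     stat="mean", bin_size=1.0)
        vals = grid[np.isfinite(grid)]
        assert np.ptp(vals) / vals.mean() < 0.2


class TestTrigger:
    def test_all_rest_day_no_positives(self):
        imu = constant_imu(7200 * 2)
        fixes = FixSeries("r", np.arange(0.0, 14400.0, 32.0),
                          np.tile([1.5, 1.5], (450, 1)))
        with pytest.warns(UserWarning, match="one class"):
            rep = motion_trigger_eval(imu, fixes, TriggerConfig(), imu_threshold=1.0)
        assert rep.tp == 0 and rep.fp == 0

    def test_confusion_counts_match_brute_force(self):
        imu, fixes, _ = coupled_data(n_sec=21600, seed=11)
        cfg = TriggerConfig()
        wins = trigger_windows(imu, fixes, cfg)
        thr = float(np.median(wins["imu_feature"]))
        rep = motion_trigger_eval(imu, fixes, cfg, imu_threshold=thr)
        pred = wins["imu_feature"].to_numpy() >= thr
        truth = wins["moved"].to_numpy()
        assert rep.tp == int((pred & truth).sum())
        assert rep.fn == int((~pred & truth).sum())
        assert rep.fp == int((pred & ~truth).sum())
        assert rep.tn == int((~pred & ~truth).sum())

    def test_sweep_monotone_sensitivity_specificity(self):
        imu, fixes, _ = coupled_data(n_sec=43200, seed=12)
        sweep = motion_trigger_eval(imu, fixes, TriggerConfig())
        s = sweep.sort_values("imu_threshold")
        sens = s["sensitivity"].to_numpy()
        spec = s["specificity"].to_numpy()
        assert (np.diff(sens) <= 1e-12).all()
        assert (np.diff(spec) >= -1e-12).all()

    def test_separable_schedule_reaches_high_sensitivity(self):
        imu, fixes, _ = coupled_data(n_sec=43200, seed=13)
        sweep = motion_trigger_eval(imu, fixes, TriggerConfig())
        ok = sweep[(sweep.sensitivity >= 0.95) & (sweep.false_negative_rate <= 0.05)]
        assert len(ok) > 0
        assert ok["specificity"].max() > 0.5  # and it is not the trivial threshold

    def test_duty_cycle_bounds_and_rest_recovery(self):
        # perfect 1-s trigger on a 76%-rest schedule suppresses ~76% of fixes
        rng = np.random.default_rng(14)
        n_sec = 86400
        active = rng.random(n_sec) < 0.24
        fixes = FixSeries("d", np.arange(0.0, n_sec, 32.0),
                          np.zeros((n_sec // 32, 2)))
        frac = duty_cycle_savings(active, 0.0, 1.0, fixes)
        assert frac == pytest.approx(0.76, abs=0.03)
        assert duty_cycle_savings(np.zeros(n_sec, bool), 0.0, 1.0, fixes) == 1.0
        assert duty_cycle_savings(np.ones(n_sec, bool), 0.0, 1.0, fixes) == 0.0


class TestBandwidth:
    @pytest.mark.parametrize("rate,axes,bits,expected", [
        (20, 3, 8, 60.0),
        (0, 3, 8, 0.0),
        (100, 3, 16, 600.0),
    ])
    def test_values(self, rate, axes, bits, expected):
        assert uplink_bandwidth(rate, axes, bits) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            uplink_bandwidth(-1, 3, 8)
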