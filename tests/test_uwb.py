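"""TDOA solver correctness, dilution-of-precision geometry, noise ellipses."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from broilertrack.layout import GeometryError, PenLayout
from broilertrack.simulate import SimConfig, make_static_noise_experiment
from broilertrack.uwb import (CHI2_95_2DOF, FixSeries, InsufficientDataError,
                              TdoaMeasurement, border_vs_center_report,
                              characterize_static_noise, gdop_covariance,
                              solve_tdoa, tdoa_residuals)

TAG_Z = 0.10


def measurement_at(p, anchors, ref=0, noise=None, rng=None):
    p3 = np.array([p[0], p[1], TAG_Z])
    r = np.linalg.norm(anchors - p3, axis=1)
    others = [i for i in range(len(anchors)) if i != ref]
    deltas = r[others] - r[ref]
    if noise:
        n = rng.normal(0.0, noise, len(anchors))
        deltas = deltas + (n[others] - n[ref])
    return TdoaMeasurement("t", 0.0, ref, deltas)


@pytest.fixture(scope="module")
def anchors(pen):
    return pen.anchor_array


class TestResiduals:
    def test_zero_at_true_position(self, anchors):
        p = (1.1, 2.3)
        res = tdoa_residuals(p, anchors, measurement_at(p, anchors))
        assert np.allclose(res, 0.0, atol=1e-12)

    def test_at_reference_anchor_closed_form(self, anchors):
        # at the reference anchor, residual_i = ||a_ref - a_i|| - delta_i
        meas = measurement_at((0.7, 0.9), anchors)
        p_ref = anchors[0, :2]
        res = tdoa_residuals(p_ref, anchors, meas, tag_height=anchors[0, 2])
        expected = np.linalg.norm(anchors[1:] - anchors[0], axis=1) - meas.delta_ranges
        assert np.allclose(res, expected, atol=1e-12)

    def test_matches_brute_force_reimplementation(self, anchors):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 3, 2)
            q = rng.uniform(0, 3, 2)
            meas = measurement_at(q, anchors, ref=2)
            res = tdoa_residuals(p, anchors, meas)
            # independent recomputation of the defining formula
            p3 = np.array([p[0], p[1], TAG_Z])
            dist = [np.sqrt(((p3 - a) ** 2).sum()) for a in anchors]
            brute = [dist[i] - dist[2] - d
                     for i, d in zip([0, 1, 3], meas.delta_ranges)]
            assert np.allclose(res, brute, atol=1e-12)

    def test_bad_reference_index_rejected(self, anchors):
        meas = TdoaMeasurement("t", 0.0, 9, np.zeros(3))
        with pytest.raises(ValueError, match="reference"):
            tdoa_residuals((1.0, 1.0), anchors, meas)


class TestSolver:
    def test_exact_inversion_center(self, anchors):
        est = solve_tdoa(measurement_at((1.5, 1.5), anchors), anchors)
        assert est.converged
        assert np.linalg.norm(est.xy - [1.5, 1.5]) < 1e-6

    def test_exact_inversion_on_coarse_grid(self, anchors):
        # 25 cm grid keeps the unit test fast; the acceptance suite runs 5 cm
        grid = np.arange(0.25, 3.0, 0.25)
        worst = 0.0
        for x in grid:
            for y in grid:
                est = solve_tdoa(measurement_at((x, y), anchors), anchors)
                worst = max(worst, float(np.hypot(est.x - x, est.y - y)))
        assert worst < 1e-6

    def test_matches_grid_search_oracle(self, anchors):
        # exhaustive 1 mm grid search minimizing the residual norm agrees
        # with the solver minimum (noiseless: both sit at the truth)
        rng = np.random.default_rng(4)
        for _ in range(2):
            p = rng.uniform(0.4, 2.6, 2)
            meas = measurement_at(p, anchors)
            est = solve_tdoa(meas, anchors)
            xs = np.arange(0.0, 3.0005, 0.001)
            best, best_cost = None, np.inf
            for y in xs:
                cand = np.column_stack([xs, np.full_like(xs, y), np.full_like(xs, TAG_Z)])
                d = np.linalg.norm(cand[:, None, :] - anchors[None], axis=2)
                res = (d[:, 1:] - d[:, [0]]) - meas.delta_ranges
                cost = (res**2).sum(axis=1)
                k = int(np.argmin(cost))
                if cost[k] < best_cost:
                    best_cost, best = cost[k], (xs[k], y)
            # grid argmin can be off the truth by at most half a cell
            assert np.hypot(est.x - best[0], est.y - best[1]) < 1.5e-3

    def test_reference_anchor_invariance_noiseless(self, anchors):
        p = (2.2, 0.8)
        sols = [solve_tdoa(measurement_at(p, anchors, ref=r), anchors).xy
                for r in range(4)]
        for s in sols[1:]:
            assert np.allclose(s, sols[0], atol=1e-8)

    def test_colinear_anchors_rejected(self):
        bad = np.array([[0, 0, 0.3], [1, 0, 0.3], [2, 0, 0.3], [3, 0, 0.3]])
        meas = TdoaMeasurement("t", 0.0, 0, np.zeros(3))
        with pytest.raises(GeometryError, match="colinear"):
            solve_tdoa(meas, bad)

    def test_fewer_than_four_anchors_rejected(self, anchors):
        meas = TdoaMeasurement("t", 0.0, 0, np.zeros(2))
        with pytest.raises(GeometryError):
            solve_tdoa(meas, anchors[:3])


class TestGdop:
    def test_center_of_square_layout_uncorrelated(self, anchors):
        cov, gdop = gdop_covariance((1.5, 1.5), anchors, 0.05)
        r = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert abs(r) < 1e-10
        assert np.isfinite(gdop)

    def test_reference_anchor_invariance(self, anchors):
        covs = [gdop_covariance((2.0, 1.0), anchors, 0.05, reference_anchor=r)[0]
                for r in range(4)]
        for c in covs[1:]:
            assert np.allclose(c, covs[0], atol=1e-15)

    def test_corner_more_correlated_than_center(self, anchors):
        def r_at(p):
            cov, _ = gdop_covariance(p, anchors, 0.05)
            return abs(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))

        assert r_at((0.2 / np.sqrt(2), 0.2 / np.sqrt(2))) > r_at((1.5, 1.5))

    def test_correlation_grows_toward_corner_anchor(self, anchors):
        # radial transect from 0.3 m off the corner anchor to the center
        d = np.linspace(0.3, 2.1, 10)
        rs = []
        for dist in d:
            p = (dist / np.sqrt(2), dist / np.sqrt(2))
            cov, _ = gdop_covariance(p, anchors, 0.05)
            rs.append(abs(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])))
        rho = spearmanr(d, rs).statistic
        assert rho < -0.8  # |r| decreases with distance from the anchor

    def test_singular_geometry_reports_infinite_gdop(self):
        coincident = np.tile([1.0, 1.0, 0.3], (4, 1))
        cov, gdop = gdop_covariance((1.0, 1.0), coincident, 0.05)
        assert np.isinf(gdop)

    def test_matches_monte_carlo_solver_covariance(self, anchors):
        p, sigma = np.array([0.6, 0.8]), 0.05
        rng = np.random.default_rng(12)
        sols = np.array([
            solve_tdoa(measurement_at(p, anchors, noise=sigma, rng=rng), anchors).xy
            for _ in range(4000)])
        mc = np.cov(sols.T)
        pred, _ = gdop_covariance(p, anchors, sigma)
        assert np.linalg.norm(mc - pred) / np.linalg.norm(pred) < 0.10


class TestNoiseEllipse:
    def test_zero_noise_degenerate_ellipse(self):
        xy = np.tile([1.0, 2.0], (100, 1))
        series = FixSeries("s", np.arange(100.0), xy)
        e = characterize_static_noise(series)
        assert e.semi_axes == (0.0, 0.0)

    def test_isotropic_closed_form(self):
        sigma, n = 0.05, 5400
        rng = np.random.default_rng(5)
        xy = rng.normal([1.5, 1.5], sigma, (n, 2))
        e = characterize_static_noise(FixSeries("i", np.arange(float(n)), xy))
        expected = sigma * np.sqrt(CHI2_95_2DOF)  # 0.1224 m
        assert e.semi_axes[0] == pytest.approx(expected, rel=0.05)
        assert e.semi_axes[1] == pytest.approx(expected, rel=0.05)

    def test_95_percent_coverage(self):
        rng = np.random.default_rng(6)
        cov = np.array([[0.004, 0.001], [0.001, 0.002]])
        xy = rng.multivariate_normal([0.5, 0.5], cov, 5400)
        series = FixSeries("c", np.arange(5400.0), xy)
        e = characterize_static_noise(series)
        assert e.contains(xy).mean() == pytest.approx(0.95, abs=0.01)

    def test_too_few_fixes_rejected(self):
        series = FixSeries("f", np.arange(10.0), np.zeros((10, 2)))
        with pytest.raises(InsufficientDataError):
            characterize_static_noise(series)

    def test_covariance_psd_and_correlation_bounded(self):
        rng = np.random.default_rng(7)
        xy = rng.normal(0, 0.1, (200, 2)) * [1.0, 0.3]
        e = characterize_static_noise(FixSeries("p", np.arange(200.0), xy))
        assert np.all(np.linalg.eigvalsh(e.covariance) >= 0)
        assert -1 <= e.xy_correlation <= 1
        assert e.semi_axes[0] >= e.semi_axes[1]


class TestBorderVsCenter:
    @pytest.fixture(scope="class")
    def experiment(self):
        runs = make_static_noise_experiment(seed=3, duration_s=43200.0)
        layout = PenLayout.noise_test_pen()
        ellipses = [characterize_static_noise(r.fixes, true_position=r.true_position)
                    for r in runs]
        return layout, runs, ellipses

    def test_border_noisier_than_center(self, experiment):
        layout, _, ellipses = experiment
        rep = border_vs_center_report(ellipses, layout)
        tbl = rep.table.set_index("label")
        assert tbl.loc["border", "mean_ellipse_area_m2"] > tbl.loc["center", "mean_ellipse_area_m2"]
        assert tbl.loc["border", "mean_abs_xy_correlation"] > tbl.loc["center", "mean_abs_xy_correlation"]

    def test_identical_positions_single_group_no_trend(self):
        rng = np.random.default_rng(8)
        layout = PenLayout.noise_test_pen()
        center = np.array(layout.center)
        ells = []
        for k in range(6):
            xy = rng.normal(center, 0.05, (200, 2))
            ells.append(characterize_static_noise(
                FixSeries(f"t{k}", np.arange(200.0), xy), true_position=center))
        rep = border_vs_center_report(ells, layout)
        assert len(rep.table) == 1
        assert not rep.monotone_trend

    def test_areas_match_gdop_prediction(self, experiment):
        # direct-mode noise is shaped by the scaled GDOP covariance, so
        # measured ellipse areas must track the analytic prediction
        layout, runs, ellipses = experiment
        cfg = SimConfig()
        cov_c, _ = gdop_covariance(layout.center, layout.anchor_array, 1.0)
        scale2 = cfg.uwb_direct_sigma_m**2 / (np.trace(cov_c) / 2.0)
        for r, e in zip(runs[:20], ellipses[:20]):
            cov, _ = gdop_covariance(r.true_position, layout.anchor_array, 1.0)
            pred_area = np.pi * CHI2_95_2DOF * np.sqrt(np.linalg.det(scale2 * cov))
            assert e.area == pytest.approx(pred_area, rel=0.15)
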