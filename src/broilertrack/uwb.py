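"""TDOA localization and position-noise characterization.

A tag transmits a single packet; synchronized anchors timestamp its
arrival. Multiplying arrival-time differences by the speed of light gives
range differences ``||p - a_i|| - ||p - a_ref||`` relative to a reference
anchor, and the tag position is the nonlinear least-squares solution of
those hyperbolic constraints. Geometry amplifies ranging noise into
position noise (dilution of precision): near an anchor the hyperbolae
become nearly parallel, so the error ellipse grows and its x/y components
become correlated, while at the center of a symmetric layout the noise is
nearly isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import GeometryError, PenLayout

__all__ = [
    "TdoaMeasurement",
    "PositionEstimate",
    "FixSeries",
    "NoiseEllipse",
    "BorderCenterReport",
    "InsufficientDataError",
    "tdoa_residuals",
    "solve_tdoa",
    "gdop_covariance",
    "characterize_static_noise",
    "border_vs_center_report",
]

# 95% mass of a bivariate Gaussian: chi-square quantile with 2 dof
CHI2_95_2DOF = 5.991464547107979

DEFAULT_TAG_HEIGHT = 0.10  # m above floor, the tag plane assumed by the solver


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested statistic."""


@dataclass(frozen=True)
class TdoaMeasurement:
    """Range differences of one packet relative to a reference anchor.

    ``delta_ranges[i]`` corresponds to the i-th non-reference anchor in
    anchor order, and equals range-to-that-anchor minus range-to-reference,
    in meters.
    """

    tag_id: object
    t: float
    reference_anchor: int
    delta_ranges: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.delta_ranges, dtype=float)
        if not np.all(np.isfinite(d)):
            raise ValueError("delta_ranges must be finite")
        object.__setattr__(self, "delta_ranges", d)


@dataclass(frozen=True)
class PositionEstimate:
    tag_id: object
    t: float
    x: float
    y: float
    residual_norm: float
    converged: bool

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class FixSeries:
    """Estimated 2-D positions of one tag at (nominally) fixed period."""

    tag_id: object
    t: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.t) != len(self.xy):
            raise ValueError("t and xy must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("fix timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tag_id": self.tag_id, "t_unix_s": self.t,
                             "x_m": self.xy[:, 0], "y_m": self.xy[:, 1]})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FixSeries":
        tag = df["tag_id"].iloc[0] if len(df) else ""
        return cls(tag, df["t_unix_s"].to_numpy(), df[["x_m", "y_m"]].to_numpy())


def _check_anchor_geometry(anchors: np.ndarray) -> None:
    anchors = np.asarray(anchors, dtype=float)
    if anchors.shape[0] < 4:
        raise GeometryError("TDOA solving needs at least 4 anchors")
    xy = anchors[:, :2]
    centered = xy - xy.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise GeometryError("anchors are colinear in the horizontal plane")


def _ranges(p_xy: np.ndarray, anchors: np.ndarray, tag_height: float) -> np.ndarray:
    p3 = np.array([p_xy[0], p_xy[1], tag_height])
    return np.linalg.norm(anchors - p3, axis=1)


def tdoa_residuals(p, anchors, meas: TdoaMeasurement,
                   tag_height: float = DEFAULT_TAG_HEIGHT) -> np.ndarray:
    """Residuals of a candidate 2-D position against measured range
    differences.

    residual_i = (||p - a_i|| - ||p - a_ref||) - delta_range_i, with
    three-dimensional tag-to-anchor ranges evaluated at the fixed tag
    height.
    """
    anchors = np.asarray(anchors, dtype=float)
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("candidate position must be finite")
    ref = meas.reference_anchor
    if not (0 <= ref < len(anchors)):
        raise ValueError(f"reference anchor index {ref} out of range for {len(anchors)} anchors")
    r = _ranges(p, anchors, tag_height)
    others = [i for i in range(len(anchors)) if i != ref]
    if len(meas.delta_ranges) != len(others):
        raise ValueError("delta_ranges length must be n_anchors - 1")
    return (r[others] - r[ref]) - meas.delta_ranges


def _whitener(n_deltas: int) -> np.ndarray:
    """Inverse square root of the TDOA noise correlation I + 11'.

    Independent per-anchor timing noise of unit variance gives the range
    *differences* covariance I + 11' (every delta shares the reference
    anchor's noise). Whitening residuals by its inverse square root makes
    ordinary least squares coincide with generalized least squares, and
    renders solutions independent of which anchor is the reference.
    """
    S = np.eye(n_deltas) + np.ones((n_deltas, n_deltas))
    evals, evecs = np.linalg.eigh(S)
    return evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T


def _tdoa_jacobian(p_xy: np.ndarray, anchors: np.ndarray, ref: int,
                   tag_height: float) -> np.ndarray:
    """Analytic Jacobian of tdoa_residuals with respect to (x, y)."""
    p3 = np.array([p_xy[0], p_xy[1], tag_height])
    diff = p3 - anchors
    r = np.linalg.norm(diff, axis=1)
    if np.any(r < 1e-12):
        r = np.maximum(r, 1e-12)
    u = diff[:, :2] / r[:, None]
    others = [i for i in range(len(anchors)) if i != ref]
    return u[others] - u[ref]


def solve_tdoa(meas: TdoaMeasurement, anchors, init=None,
               tag_height: float = DEFAULT_TAG_HEIGHT,
               max_iter: int = 100) -> PositionEstimate:
    """Solve one TDOA measurement for a 2-D position.

    Nonlinear generalized least squares: residuals are whitened by the
    inverse square root of the TDOA noise correlation (I + 11'), which
    makes the estimate independent of the reference-anchor choice, and
    minimized with ``scipy.optimize.least_squares`` using the analytic
    Jacobian, initialized at the anchor centroid. Convergence is declared
    when the step falls below ~1e-9 m or the residual gradient below
    1e-12; non-convergence is reported through the ``converged`` flag,
    never silently.
    """
    from scipy.optimize import least_squares

    anchors = np.asarray(anchors, dtype=float)
    _check_anchor_geometry(anchors)
    ref = meas.reference_anchor
    if not (0 <= ref < len(anchors)):
        raise ValueError(f"reference anchor index {ref} out of range for {len(anchors)} anchors")
    p0 = np.asarray(init, dtype=float)[:2] if init is not None else anchors[:, :2].mean(axis=0)
    W = _whitener(len(anchors) - 1)

    result = least_squares(
        lambda p: W @ tdoa_residuals(p, anchors, meas, tag_height),
        p0,
        jac=lambda p: W @ _tdoa_jacobian(p, anchors, ref, tag_height),
        method="lm",
        xtol=1e-12, ftol=1e-15, gtol=1e-12, max_nfev=max_iter * 4,
    )
    p = result.x
    res = tdoa_residuals(p, anchors, meas, tag_height)
    converged = bool(result.status in (1, 2, 3, 4) and np.all(np.isfinite(p)))
    return PositionEstimate(meas.tag_id, meas.t, float(p[0]), float(p[1]),
                            float(np.linalg.norm(res)), converged)


def gdop_covariance(p, anchors, range_sigma: float,
                    reference_anchor: int = 0,
                    tag_height: float = DEFAULT_TAG_HEIGHT):
    """Position-error covariance implied by geometry at a point.

    ``range_sigma`` is the per-anchor timing noise expressed in meters;
    the range differences then have covariance sigma^2 (I + 11') and the
    generalized-least-squares position covariance is
    sigma^2 (J' (I + 11')^{-1} J)^{-1} with J the Jacobian of
    :func:`tdoa_residuals` at ``p``. The result does not depend on the
    reference-anchor choice. The scalar dilution-of-precision figure is
    sqrt(trace(cov)) / sigma. Singular geometry yields an infinite GDOP
    rather than an exception.

    Returns
    -------
    (cov, gdop) : 2x2 ndarray (m^2) and float.
    """
    anchors = np.asarray(anchors, dtype=float)
    p = np.asarray(p, dtype=float)[:2]
    J = _tdoa_jacobian(p, anchors, reference_anchor, tag_height)
    m = len(anchors) - 1
    # (I + 11')^{-1} = I - 11'/(1+m)  (Sherman-Morrison)
    Winv = np.eye(m) - np.ones((m, m)) / (1.0 + m)
    JtJ = J.T @ Winv @ J
    det = np.linalg.det(JtJ)
    if not np.isfinite(det) or det < 1e-300:
        inf = np.full((2, 2), np.inf)
        return inf, np.inf
    cov = range_sigma**2 * np.linalg.inv(JtJ)
    gdop = float(np.sqrt(np.trace(cov)) / range_sigma)
    return cov, gdop


@dataclass(frozen=True)
class NoiseEllipse:
    """95% confidence ellipse of a static tag's reported positions."""

    tag_id: object
    mean: np.ndarray
    covariance: np.ndarray
    semi_axes: tuple[float, float]       # (a, b), a >= b, meters
    orientation_angle: float             # radians, major axis vs +x
    xy_correlation: float
    n_fixes: int = 0
    true_position: np.ndarray | None = None

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Whether points fall inside the 95% ellipse (Mahalanobis test)."""
        xy = np.atleast_2d(xy) - self.mean
        cov = self.covariance
        if np.linalg.det(cov) <= 0:
            return np.zeros(len(xy), dtype=bool)
        inv = np.linalg.inv(cov)
        d2 = np.einsum("ni,ij,nj->n", xy, inv, xy)
        return d2 <= CHI2_95_2DOF


def characterize_static_noise(series: FixSeries,
                              true_position=None) -> NoiseEllipse:
    """Mean, covariance and 95% confidence ellipse of a static tag.

    Semi-axes are sqrt(5.991 * eigenvalue) of the sample covariance
    (chi-square with 2 dof at 95%). Requires at least 30 fixes.
    """
    if len(series) < 30:
        raise InsufficientDataError(
            f"need >= 30 fixes to characterize noise, got {len(series)}")
    xy = series.xy
    mean = xy.mean(axis=0)
    cov = np.cov(xy.T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    a, b = np.sqrt(CHI2_95_2DOF * evals)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    sx, sy = np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])
    r = float(cov[0, 1] / (sx * sy)) if sx > 0 and sy > 0 else 0.0
    tp = None if true_position is None else np.asarray(true_position, dtype=float)
    return NoiseEllipse(series.tag_id, mean, cov, (float(a), float(b)), angle,
                        r, n_fixes=len(series), true_position=tp)


@dataclass(frozen=True)
class BorderCenterReport:
    """Noise summaries grouped by distance to the nearest anchor."""

    table: pd.DataFrame
    monotone_trend: bool


def border_vs_center_report(ellipses, layout: PenLayout,
                            n_groups: int = 3) -> BorderCenterReport:
    """Group static-tag ellipses by distance to the nearest anchor and
    summarize error size per group.

    Tags near the pen border sit close to anchors, where dilution of
    precision inflates and correlates the noise; the report orders groups
    from nearest ("border") to farthest ("center") and flags whether the
    mean ellipse area decreases monotonically with distance from anchors.
    """
    rows = []
    for e in ellipses:
        pos = e.true_position if e.true_position is not None else e.mean
        d = float(layout.distance_to_nearest_anchor(pos)[0])
        rows.append({"tag_id": e.tag_id, "anchor_distance_m": d,
                     "area_m2": e.area, "abs_xy_correlation": abs(e.xy_correlation)})
    df = pd.DataFrame(rows)
    if df["anchor_distance_m"].nunique() < n_groups:
        groups = pd.Series(0, index=df.index)
        n_groups = 1
    else:
        groups = pd.qcut(df["anchor_distance_m"], n_groups, labels=False, duplicates="drop")
        n_groups = int(groups.max()) + 1
    df["group"] = groups
    summary = (df.groupby("group")
                 .agg(n_tags=("tag_id", "size"),
                      mean_anchor_distance_m=("anchor_distance_m", "mean"),
                      mean_ellipse_area_m2=("area_m2", "mean"),
                      mean_abs_xy_correlation=("abs_xy_correlation", "mean"))
                 .reset_index())
    labels = {0: "border"}
    if n_groups > 1:
        labels[n_groups - 1] = "center"
    for g in range(1, max(n_groups - 1, 1)):
        labels.setdefault(g, f"mid_{g}")
    summary["label"] = summary["group"].map(labels)
    areas = summary["mean_ellipse_area_m2"].to_numpy()
    trend = bool(len(areas) > 1 and np.all(np.diff(areas) < 0))
    return BorderCenterReport(summary, trend)
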