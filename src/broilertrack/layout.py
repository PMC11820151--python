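"""Pen geometry, anchor placement, light schedules and sensor mounts.

Coordinates are metric: origin at the pen's south-west corner, x to the
east, y to the north, z up. Anchors carry a height (z) because true
tag-to-anchor ranges are three-dimensional even though positions are
reported in 2-D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Attractor",
    "PenLayout",
    "LightSchedule",
    "MountOrientation",
    "GeometryError",
]

ATTRACTOR_LABELS = ("feeder", "drinker")


class GeometryError(ValueError):
    """Raised for degenerate anchor geometry or out-of-pen attractors."""


@dataclass(frozen=True)
class Attractor:
    """A zone that draws birds to it (feeder or drinker)."""

    label: str
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.label not in ATTRACTOR_LABELS:
            raise ValueError(f"attractor label must be one of {ATTRACTOR_LABELS}, got {self.label!r}")
        if self.radius <= 0:
            raise ValueError("attractor radius must be > 0")


@dataclass(frozen=True)
class PenLayout:
    """Rectangular pen with UWB anchors and attractor zones.

    Parameters
    ----------
    width, height
        Pen dimensions in meters.
    anchors
        Sequence of (x, y, z) anchor coordinates in meters. Localization
        requires at least four non-colinear anchors.
    attractors
        Feeder/drinker zones; centers must lie inside the pen rectangle.
    """

    width: float
    height: float
    anchors: tuple[tuple[float, float, float], ...] = ()
    attractors: tuple[Attractor, ...] = ()

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("pen width and height must be > 0")
        object.__setattr__(self, "anchors", tuple(tuple(float(c) for c in a) for a in self.anchors))
        object.__setattr__(self, "attractors", tuple(self.attractors))
        for a in self.anchors:
            if len(a) != 3:
                raise ValueError("anchors must be (x, y, z) triples")
        for att in self.attractors:
            x, y = att.center
            if not (0 <= x <= self.width and 0 <= y <= self.height):
                raise GeometryError(f"attractor {att.label!r} center {att.center} lies outside the pen")

    # -- geometry helpers -------------------------------------------------

    @property
    def anchor_array(self) -> np.ndarray:
        """Anchors as an (n, 3) float array."""
        return np.asarray(self.anchors, dtype=float)

    @property
    def center(self) -> tuple[float, float]:
        return (self.width / 2.0, self.height / 2.0)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return (
            (xy[:, 0] >= 0) & (xy[:, 0] <= self.width) & (xy[:, 1] >= 0) & (xy[:, 1] <= self.height)
        )

    def clip(self, xy: np.ndarray) -> np.ndarray:
        xy = np.array(xy, dtype=float)
        xy[..., 0] = np.clip(xy[..., 0], 0.0, self.width)
        xy[..., 1] = np.clip(xy[..., 1], 0.0, self.height)
        return xy

    def attractors_of(self, label: str) -> tuple[Attractor, ...]:
        return tuple(a for a in self.attractors if a.label == label)

    def distance_to_nearest_anchor(self, xy) -> np.ndarray:
        """Planar distance from point(s) to the closest anchor."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        axy = self.anchor_array[:, :2]
        d = np.linalg.norm(xy[:, None, :] - axy[None, :, :], axis=-1)
        return d.min(axis=1)

    # -- canned layouts ----------------------------------------------------

    @classmethod
    def square_pen(cls, side: float = 3.0, anchor_z: float = 0.30,
                   attractors: tuple[Attractor, ...] | None = None) -> "PenLayout":
        """Square rearing pen with four corner anchors ~30 cm above floor.

        Default attractors mimic the second-round pen: two feeders in the
        center region and drinkers along the left wall.
        """
        anchors = ((0.0, 0.0, anchor_z), (side, 0.0, anchor_z),
                   (side, side, anchor_z), (0.0, side, anchor_z))
        if attractors is None:
            attractors = (
                Attractor("feeder", (side * 0.45, side * 0.5), 0.25),
                Attractor("feeder", (side * 0.62, side * 0.5), 0.25),
                Attractor("drinker", (side * 0.08, side * 0.5), 0.20),
            )
        return cls(side, side, anchors, attractors)

    @classmethod
    def noise_test_pen(cls, width: float = 9.0, height: float = 4.0,
                       anchor_z: float = 0.30) -> "PenLayout":
        """9 m x 4 m static-noise pen with six anchors: four corners plus
        the midpoints of the two long walls."""
        anchors = (
            (0.0, 0.0, anchor_z), (width, 0.0, anchor_z),
            (width, height, anchor_z), (0.0, height, anchor_z),
            (width / 2.0, 0.0, anchor_z), (width / 2.0, height, anchor_z),
        )
        return cls(width, height, anchors)


@dataclass(frozen=True)
class LightSchedule:
    """Daily lighting regime given as dark intervals in local clock hours.

    Intervals may wrap midnight (e.g. ``(20, 24)`` plus ``(0, 2)`` is
    equivalent to a single wrapped ``(20, 2)``).
    """

    dark_intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b)) for a, b in self.dark_intervals)
        object.__setattr__(self, "dark_intervals", ivs)
        mask = self._dark_mask()
        # non-overlap check on a fine grid of the day
        total = sum(self._interval_hours(a, b) for a, b in ivs)
        if abs(mask.mean() * 24.0 - total) > 1e-6:
            raise ValueError("dark intervals overlap")

    @staticmethod
    def _interval_hours(a: float, b: float) -> float:
        return (b - a) % 24.0 if a != b else 0.0

    def _dark_mask(self, resolution: int = 86400) -> np.ndarray:
        h = np.arange(resolution) * (24.0 / resolution)
        mask = np.zeros(resolution, dtype=bool)
        for a, b in self.dark_intervals:
            if a <= b:
                mask |= (h >= a) & (h < b)
            else:  # wraps midnight
                mask |= (h >= a) | (h < b)
        return mask

    @property
    def dark_hours(self) -> float:
        return sum(self._interval_hours(a, b) for a, b in self.dark_intervals)

    def is_dark(self, hour_of_day) -> np.ndarray:
        """Vectorized dark/light lookup for clock hours in [0, 24)."""
        h = np.asarray(hour_of_day, dtype=float) % 24.0
        out = np.zeros(h.shape, dtype=bool)
        for a, b in self.dark_intervals:
            if a <= b:
                out |= (h >= a) & (h < b)
            else:
                out |= (h >= a) | (h < b)
        return out

    def next_transition_hour(self, hour_of_day: float) -> float:
        """Clock hour of the next dark/light boundary strictly after now."""
        h = float(hour_of_day) % 24.0
        bounds = sorted({a % 24.0 for iv in self.dark_intervals for a in iv})
        for b in bounds:
            if b > h + 1e-12:
                return b
        return bounds[0] + 24.0 if bounds else h + 24.0

    @classmethod
    def broiler_16L8D(cls) -> "LightSchedule":
        """Standard 16 h light / 8 h dark schedule with dark 02:00-06:00
        and 20:00-24:00."""
        return cls(((2.0, 6.0), (20.0, 24.0)))


@dataclass(frozen=True)
class MountOrientation:
    """Per-bird sensor mounting as a rigid rotation.

    The rotation maps the sensor's body frame to the world frame; a
    motionless, level sensor with the identity mount reads (0, 0, 1) g.
    Mount differences between birds shift per-axis accelerations but never
    the magnitude.
    """

    tag_id: object
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("mount rotation must be a 3x3 orthonormal matrix")
        object.__setattr__(self, "rotation", R)

    @property
    def gravity_reading(self) -> np.ndarray:
        """Accelerometer reading (in g) of this mount at rest."""
        return self.rotation @ np.array([0.0, 0.0, 1.0])

    @classmethod
    def identity(cls, tag_id: object) -> "MountOrientation":
        return cls(tag_id, np.eye(3))

    @classmethod
    def random(cls, tag_id: object, rng: np.random.Generator) -> "MountOrientation":
        return cls(tag_id, Rotation.random(random_state=rng).as_matrix())

    @classmethod
    def from_euler(cls, tag_id: object, roll: float, pitch: float, yaw: float,
                   degrees: bool = True) -> "MountOrientation":
        return cls(tag_id, Rotation.from_euler("xyz", [roll, pitch, yaw], degrees=degrees).as_matrix())
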