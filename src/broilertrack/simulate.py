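"""Synthetic pen simulator: behavior, trajectories, IMU traces, UWB fixes.

The simulator provides ground truth with the statistical structure the
downstream analyses assume: broilers that are inactive for roughly three
quarters of the day, more so during the dark phase of a 16L:8D light
schedule; movement concentrated around feeders and drinkers; a 20 Hz
tri-axial accelerometer whose resting magnitude is 1 g regardless of how
the sensor is mounted on the bird; and UWB fixes every 32 s whose noise
grows and becomes x/y-correlated near the anchors.

Behavior is a four-state continuous-time Markov chain over
REST / FORAGE / DRINK / WALK. Rest bouts alternate with activity bouts;
phase-dependent exponential dwell times are calibrated so the stationary
REST fraction hits a target overall (default 0.76) and is higher in the
dark than in the light. The chain is time-inhomogeneous across light
transitions: thanks to the memoryless property, re-drawing the remaining
dwell at each phase boundary with the new phase's rate is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import rng_stream
from .layout import GeometryError, LightSchedule, MountOrientation, PenLayout
from .uwb import (
    DEFAULT_TAG_HEIGHT,
    FixSeries,
    TdoaMeasurement,
    gdop_covariance,
    solve_tdoa,
)

__all__ = [
    "STATES",
    "SimConfig",
    "BehaviorSchedule",
    "Trajectory",
    "ImuTrace",
    "StaticTagRun",
    "simulate_behavior",
    "simulate_trajectory",
    "synthesize_imu",
    "synthesize_uwb_fixes",
    "make_static_noise_experiment",
]

REST, FORAGE, DRINK, WALK = "REST", "FORAGE", "DRINK", "WALK"
STATES = (REST, FORAGE, DRINK, WALK)
ACTIVE_STATES = (FORAGE, DRINK, WALK)
STATE_CODE = {s: i for i, s in enumerate(STATES)}


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Parameters
    ----------
    seed
        Master seed; every tag and stage derives an independent stream.
    duration_s
        Simulated span in seconds.
    uwb_period_s, imu_rate_hz
        UWB fix period (default 32 s) and accelerometer rate (default
        20 Hz).
    rest_fraction_target
        Desired overall REST fraction of the day (default 0.76).
    dark_rest_fraction
        REST fraction during dark hours; the light-phase fraction is
        derived so the 24 h mixture hits the overall target.
    mean_active_bout_light_s, mean_active_bout_dark_s
        Mean duration of an activity bout per light phase.
    activity_probs
        Probabilities of entering FORAGE / DRINK / WALK when leaving REST.
    walk_speed_mps, max_speed_mps
        Typical and maximal ground speed.
    imu_noise_sd_g, activity_burst_sd_g
        Per-axis white sensor noise, and the extra per-axis burst noise
        present only while the bird is active.
    uwb_direct_sigma_m
        Per-axis position noise at the pen center for direct-mode fixes.
    uwb_range_sigma_m
        Range-difference noise for solver-mode fixes.
    start_hour
        Clock hour at t=0 (light schedule anchor).
    """

    seed: int = 0
    duration_s: float = 86400.0
    uwb_period_s: float = 32.0
    imu_rate_hz: float = 20.0
    rest_fraction_target: float = 0.76
    dark_rest_fraction: float = 0.92
    mean_active_bout_light_s: float = 60.0
    mean_active_bout_dark_s: float = 30.0
    activity_probs: tuple[float, float, float] = (0.4, 0.2, 0.4)
    walk_speed_mps: float = 0.25
    max_speed_mps: float = 0.5
    step_s: float = 1.0
    imu_noise_sd_g: float = 0.01
    activity_burst_sd_g: float = 0.2
    uwb_direct_sigma_m: float = 0.08
    uwb_range_sigma_m: float = 0.05
    tag_height_m: float = DEFAULT_TAG_HEIGHT
    start_hour: float = 0.0

    def __post_init__(self) -> None:
        positive = ["duration_s", "uwb_period_s", "imu_rate_hz", "step_s",
                    "mean_active_bout_light_s", "mean_active_bout_dark_s",
                    "walk_speed_mps", "max_speed_mps"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not (0.0 < self.rest_fraction_target <= 1.0):
            raise ValueError(f"rest_fraction_target must be in (0, 1], got {self.rest_fraction_target}")
        if not (0.0 < self.dark_rest_fraction <= 1.0):
            raise ValueError(f"dark_rest_fraction must be in (0, 1], got {self.dark_rest_fraction}")
        p = np.asarray(self.activity_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("activity_probs must be 3 non-negative values summing to 1")
        for name in ["imu_noise_sd_g", "activity_burst_sd_g", "uwb_direct_sigma_m",
                     "uwb_range_sigma_m"]:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def phase_rest_fractions(self, schedule: LightSchedule) -> tuple[float, float]:
        """(light, dark) REST fractions consistent with the overall target.

        With dark fraction d of the day, solve
        (1-d) * p_light + d * p_dark = target.
        """
        if self.rest_fraction_target >= 1.0:
            return 1.0, 1.0
        d = schedule.dark_hours / 24.0
        p_dark = min(self.dark_rest_fraction, 1.0)
        if d >= 1.0:
            return p_dark, p_dark
        p_light = (self.rest_fraction_target - d * p_dark) / (1.0 - d)
        if not (0.0 < p_light < 1.0):
            raise ValueError(
                "dark_rest_fraction is incompatible with rest_fraction_target "
                f"under this light schedule (implied light fraction {p_light:.3f})")
        return p_light, p_dark


@dataclass(frozen=True)
class BehaviorSchedule:
    """Contiguous behavioral segments of one bird."""

    tag_id: object
    segments: tuple[tuple[float, float, str], ...]  # (t_start, t_end, state)

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b), s) for a, b, s in self.segments)
        for (a, b, s), nxt in zip(segs, segs[1:] + (None,)):
            if b <= a:
                raise ValueError("segments must have positive duration")
            if s not in STATES:
                raise ValueError(f"unknown state {s!r}")
            if nxt is not None and abs(nxt[0] - b) > 1e-9:
                raise ValueError("segments must be contiguous")
        object.__setattr__(self, "segments", segs)

    @property
    def duration(self) -> float:
        return self.segments[-1][1] - self.segments[0][0]

    def state_fraction(self, state: str, t0: float | None = None,
                       t1: float | None = None) -> float:
        """Time fraction spent in ``state`` within [t0, t1]."""
        lo = self.segments[0][0] if t0 is None else t0
        hi = self.segments[-1][1] if t1 is None else t1
        tot = acc = 0.0
        for a, b, s in self.segments:
            ov = max(0.0, min(b, hi) - max(a, lo))
            tot += ov
            if s == state:
                acc += ov
        return acc / tot if tot > 0 else float("nan")

    def rest_fraction(self) -> float:
        return self.state_fraction(REST)

    def rest_fraction_by_phase(self, schedule: LightSchedule,
                               start_hour: float = 0.0) -> tuple[float, float]:
        """(light, dark) REST fractions realized under a light schedule."""
        tot = {"light": 0.0, "dark": 0.0}
        rest = {"light": 0.0, "dark": 0.0}
        for a, b, s in self.segments:
            # split each segment at phase boundaries
            t = a
            while t < b - 1e-9:
                h = (start_hour + t / 3600.0) % 24.0
                nxt_h = schedule.next_transition_hour(h)
                t_next = min(b, t + (nxt_h - h) * 3600.0)
                phase = "dark" if schedule.is_dark(h) else "light"
                tot[phase] += t_next - t
                if s == REST:
                    rest[phase] += t_next - t
                t = t_next
        fl = rest["light"] / tot["light"] if tot["light"] > 0 else float("nan")
        fd = rest["dark"] / tot["dark"] if tot["dark"] > 0 else float("nan")
        return fl, fd

    def states_per_step(self, step_s: float = 1.0) -> np.ndarray:
        """Integer state codes sampled at step midpoints over the span."""
        t0, t1 = self.segments[0][0], self.segments[-1][1]
        n = int(round((t1 - t0) / step_s))
        mid = t0 + (np.arange(n) + 0.5) * step_s
        edges = np.array([a for a, _, _ in self.segments] + [t1])
        idx = np.clip(np.searchsorted(edges, mid, side="right") - 1, 0, len(self.segments) - 1)
        codes = np.array([STATE_CODE[s] for _, _, s in self.segments])
        return codes[idx]


@dataclass
class Trajectory:
    """Ground-truth 2-D path at a fine internal step (default 1 s)."""

    tag_id: object
    t: np.ndarray
    xy: np.ndarray
    step_s: float = 1.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.t) != len(self.xy):
            raise ValueError("t and xy must align")

    def path_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.xy, axis=0), axis=1).sum())


@dataclass
class ImuTrace:
    """20 Hz tri-axial acceleration in g."""

    tag_id: object
    rate_hz: float
    t: np.ndarray
    samples: np.ndarray  # (n, 3) ax, ay, az in g

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1, 3)
        if self.rate_hz <= 0:
            raise ValueError("imu rate must be > 0")
        if len(self.t) != len(self.samples):
            raise ValueError("t and samples must align")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("IMU timestamps must be strictly increasing")
            nominal = 1.0 / self.rate_hz
            if np.any(np.abs(dt - nominal) > 0.5 * nominal):
                raise ValueError("IMU timestamps deviate from the nominal rate")


def _phase_of(t: float, config: SimConfig, schedule: LightSchedule) -> bool:
    """True if dark at simulation time t."""
    return bool(schedule.is_dark((config.start_hour + t / 3600.0) % 24.0))


def simulate_behavior(config: SimConfig, schedule: LightSchedule,
                      tag_id: object = 0) -> BehaviorSchedule:
    """Simulate the four-state behavior chain for one bird.

    REST alternates with activity bouts (FORAGE / DRINK / WALK chosen by
    ``activity_probs``). Dwell times are exponential with phase-dependent
    means: activity bouts average ``mean_active_bout_*_s`` and REST dwells
    are scaled so each phase realizes its calibrated REST fraction, which
    makes the dark phase strictly rest-dominant over the light phase.
    """
    if config.duration_s < 3600.0:
        raise ValueError("duration_s must be >= 1 h for fraction targets to be meaningful")
    p_light, p_dark = config.phase_rest_fractions(schedule)
    rng = rng_stream(config.seed, tag_id, "behavior")

    def rest_mean(dark: bool) -> float:
        p = p_dark if dark else p_light
        active = config.mean_active_bout_dark_s if dark else config.mean_active_bout_light_s
        if p >= 1.0:
            return float("inf")
        return active * p / (1.0 - p)

    def active_mean(dark: bool) -> float:
        return config.mean_active_bout_dark_s if dark else config.mean_active_bout_light_s

    segments: list[tuple[float, float, str]] = []
    t, state = 0.0, REST
    while t < config.duration_s - 1e-9:
        dark = _phase_of(t, config, schedule)
        h = (config.start_hour + t / 3600.0) % 24.0
        boundary = t + (schedule.next_transition_hour(h) - h) * 3600.0
        mean = rest_mean(dark) if state == REST else active_mean(dark)
        dwell = float("inf") if not np.isfinite(mean) else rng.exponential(mean)
        seg_end = min(t + dwell, boundary, config.duration_s)
        if seg_end > t:
            segments.append((t, seg_end, state))
        if seg_end == boundary and seg_end < min(t + dwell, config.duration_s):
            t = seg_end  # phase change: re-draw dwell, keep state (memoryless)
            continue
        t = seg_end
        if t >= config.duration_s - 1e-9:
            break
        if state == REST:
            state = ACTIVE_STATES[rng.choice(3, p=np.asarray(config.activity_probs))]
        else:
            state = REST

    # merge contiguous same-state segments
    merged: list[tuple[float, float, str]] = []
    for a, b, s in segments:
        if merged and merged[-1][2] == s and abs(merged[-1][1] - a) < 1e-9:
            merged[-1] = (merged[-1][0], b, s)
        else:
            merged.append((a, b, s))
    return BehaviorSchedule(tag_id, tuple(merged))


def _nearest_attractor(layout: PenLayout, label: str, pos: np.ndarray):
    cands = layout.attractors_of(label)
    dists = [np.linalg.norm(np.asarray(a.center) - pos) for a in cands]
    return cands[int(np.argmin(dists))]


def simulate_trajectory(schedule: BehaviorSchedule, layout: PenLayout,
                        config: SimConfig) -> Trajectory:
    """Turn a behavior schedule into a bounded-speed 2-D path.

    REST is stationary. FORAGE/DRINK birds head to the nearest matching
    attractor at walking speed and then jitter inside its radius. WALK is
    a correlated random walk (persistent heading with turning noise)
    reflected at the pen walls. Displacement per step never exceeds
    ``max_speed_mps * step_s`` and positions stay inside the pen.
    """
    if not layout.attractors_of("feeder") or not layout.attractors_of("drinker"):
        raise GeometryError("layout needs at least one feeder and one drinker attractor")
    rng = rng_stream(config.seed, schedule.tag_id, "trajectory")
    step = config.step_s
    states = schedule.states_per_step(step)
    n = len(states)
    t0 = schedule.segments[0][0]

    pos = np.array(layout.center, dtype=float)
    heading = rng.uniform(0, 2 * np.pi)
    out = np.empty((n + 1, 2))
    out[0] = pos
    v_walk = min(config.walk_speed_mps, config.max_speed_mps)
    code_rest = STATE_CODE[REST]
    target_attr = None
    prev_code = -1

    for i in range(n):
        code = states[i]
        state = STATES[code]
        if code != prev_code:
            label = {FORAGE: "feeder", DRINK: "drinker"}.get(state)
            target_attr = _nearest_attractor(layout, label, pos) if label else None
            prev_code = code
        if code == code_rest:
            pass
        elif state in (FORAGE, DRINK):
            center = np.asarray(target_attr.center)
            delta = center - pos
            dist = np.linalg.norm(delta)
            if dist > target_attr.radius:
                stride = min(v_walk * step, dist)
                pos = pos + delta / dist * stride
            else:
                jitter = rng.normal(0.0, 0.03, size=2)
                cand = pos + jitter
                if np.linalg.norm(cand - center) > target_attr.radius:
                    cand = pos
                pos = cand
        else:  # WALK: correlated random walk
            heading += rng.normal(0.0, 0.6)
            stride = v_walk * step
            cand = pos + stride * np.array([np.cos(heading), np.sin(heading)])
            # reflect at walls
            if cand[0] < 0:
                cand[0] = -cand[0]
                heading = np.pi - heading
            elif cand[0] > layout.width:
                cand[0] = 2 * layout.width - cand[0]
                heading = np.pi - heading
            if cand[1] < 0:
                cand[1] = -cand[1]
                heading = -heading
            elif cand[1] > layout.height:
                cand[1] = 2 * layout.height - cand[1]
                heading = -heading
            pos = layout.clip(cand)
        out[i + 1] = pos

    t = t0 + np.arange(n + 1) * step
    return Trajectory(schedule.tag_id, t, out, step_s=step)


def synthesize_imu(schedule: BehaviorSchedule, mount: MountOrientation,
                   config: SimConfig) -> ImuTrace:
    """Generate a tri-axial accelerometer trace from a behavior schedule.

    Each sample is the mount-rotated gravity unit vector plus white sensor
    noise on every axis, plus extra activity-burst noise on every axis
    while the bird is not resting. Noiseless resting samples therefore
    have magnitude exactly 1 g for any mount.
    """
    if config.activity_burst_sd_g < config.imu_noise_sd_g:
        warnings.warn(
            "activity_burst_sd_g < imu_noise_sd_g: active and inactive samples "
            "will not be separable as configured", stacklevel=2)
    rng = rng_stream(config.seed, schedule.tag_id, "imu")
    rate = config.imu_rate_hz
    per_sec = int(round(rate))
    states = schedule.states_per_step(1.0)
    n = len(states) * per_sec
    t0 = schedule.segments[0][0]
    t = t0 + np.arange(n) / rate

    gravity = mount.gravity_reading
    samples = np.tile(gravity, (n, 1))
    if config.imu_noise_sd_g > 0:
        samples += rng.normal(0.0, config.imu_noise_sd_g, size=(n, 3))
    active = np.repeat(states != STATE_CODE[REST], per_sec)
    n_active = int(active.sum())
    if n_active and config.activity_burst_sd_g > 0:
        samples[active] += rng.normal(0.0, config.activity_burst_sd_g, size=(n_active, 3))
    return ImuTrace(schedule.tag_id, rate, t, samples)


def synthesize_uwb_fixes(traj: Trajectory, layout: PenLayout, config: SimConfig,
                         mode: str = "direct") -> FixSeries:
    """Sample a trajectory every UWB period and add position noise.

    ``direct`` mode draws Gaussian noise shaped by the local
    geometric-dilution covariance, scaled so the per-axis sd at the pen
    center equals ``uwb_direct_sigma_m``. ``solver`` mode generates TDOA
    range differences with Gaussian noise ``uwb_range_sigma_m`` and runs
    the nonlinear solver; it requires at least four anchors.
    """
    if mode not in ("direct", "solver"):
        raise ValueError(f"mode must be 'direct' or 'solver', got {mode!r}")
    anchors = layout.anchor_array
    if mode == "solver" and len(anchors) < 4:
        raise GeometryError("solver mode requires at least 4 anchors")
    rng = rng_stream(config.seed, traj.tag_id, f"uwb_{mode}")
    t0, t1 = traj.t[0], traj.t[-1]
    if t1 - t0 < config.uwb_period_s:
        warnings.warn("trajectory shorter than one UWB period: empty fix series",
                      stacklevel=2)
        return FixSeries(traj.tag_id, np.empty(0), np.empty((0, 2)))
    # half-open sampling: a span of exactly k periods yields k fixes
    times = t0 + np.arange(int(np.ceil((t1 - t0) / config.uwb_period_s - 1e-9))) * config.uwb_period_s
    idx = np.clip(np.round((times - t0) / traj.step_s).astype(int), 0, len(traj.t) - 1)
    truth = traj.xy[idx]

    if mode == "direct":
        # reference covariance shape with unit range noise, rescaled so the
        # per-axis sd at the pen center matches uwb_direct_sigma_m
        cov_c, _ = gdop_covariance(layout.center, anchors, 1.0,
                                   tag_height=config.tag_height_m)
        scale2 = config.uwb_direct_sigma_m**2 / (np.trace(cov_c) / 2.0)
        z = rng.standard_normal((len(truth), 2))
        est = np.empty_like(truth)
        static = bool(np.all(truth == truth[0]))
        if static:
            cov, _ = gdop_covariance(truth[0], anchors, 1.0,
                                     tag_height=config.tag_height_m)
            if np.all(np.isfinite(cov)) and scale2 > 0:
                L = np.linalg.cholesky(scale2 * (cov + 1e-15 * np.eye(2)))
                est = truth + z @ L.T
            else:
                est = truth.copy()
            return FixSeries(traj.tag_id, times, est)
        for k, p in enumerate(truth):
            cov, _ = gdop_covariance(p, anchors, 1.0, tag_height=config.tag_height_m)
            if not np.all(np.isfinite(cov)) or scale2 <= 0:
                est[k] = p
                continue
            L = np.linalg.cholesky(scale2 * (cov + 1e-15 * np.eye(2)))
            est[k] = p + L @ z[k]
        return FixSeries(traj.tag_id, times, est)

    # solver mode: synthesize noisy range differences, then invert
    est = np.empty_like(truth)
    dropped = 0
    for k, p in enumerate(truth):
        p3 = np.array([p[0], p[1], config.tag_height_m])
        r = np.linalg.norm(anchors - p3, axis=1)
        deltas = r[1:] - r[0]
        if config.uwb_range_sigma_m > 0:
            # independent timing noise per anchor; deltas share the
            # reference anchor's noise term
            n_noise = rng.normal(0.0, config.uwb_range_sigma_m, size=len(anchors))
            deltas = deltas + (n_noise[1:] - n_noise[0])
        meas = TdoaMeasurement(traj.tag_id, float(times[k]), 0, deltas)
        sol = solve_tdoa(meas, anchors, tag_height=config.tag_height_m)
        if not sol.converged:
            dropped += 1
        est[k] = sol.xy
    if dropped:
        warnings.warn(f"{dropped} of {len(truth)} solver fixes did not converge",
                      stacklevel=2)
    return FixSeries(traj.tag_id, times, est)


@dataclass(frozen=True)
class StaticTagRun:
    """One motionless tag of the noise experiment."""

    pen_index: int
    tag_id: str
    true_position: np.ndarray
    fixes: FixSeries


def make_static_noise_experiment(seed: int = 0, n_pens: int = 4,
                                 tags_per_pen: int = 20,
                                 duration_s: float = 86400.0,
                                 period_s: float = 16.0,
                                 layout: PenLayout | None = None,
                                 mode: str = "direct",
                                 sigma: float | None = None,
                                 grid_margin: float = 0.35) -> list[StaticTagRun]:
    """Static-tag noise experiment: motionless tags logged for 24 h.

    Tags are laid out on a deterministic grid in each pen (default four
    9 m x 4 m pens with six anchors, 20 tags each, 1/16 Hz for 24 h, i.e.
    5400 fixes per tag). Returns one :class:`StaticTagRun` per tag with
    its true grid position attached.
    """
    layout = layout or PenLayout.noise_test_pen()
    cols = int(np.ceil(np.sqrt(tags_per_pen * layout.width / layout.height)))
    rows = int(np.ceil(tags_per_pen / cols))
    if cols * rows < tags_per_pen:
        raise ValueError("grid capacity insufficient for requested tags_per_pen")
    xs = np.linspace(grid_margin, layout.width - grid_margin, cols)
    ys = np.linspace(grid_margin, layout.height - grid_margin, rows)
    grid = [(x, y) for y in ys for x in xs][:tags_per_pen]

    runs: list[StaticTagRun] = []
    for pen in range(n_pens):
        for k, (x, y) in enumerate(grid):
            tag = f"pen{pen}_tag{k:02d}"
            cfg = SimConfig(seed=seed, duration_s=duration_s, uwb_period_s=period_s,
                            **({"uwb_direct_sigma_m": sigma} if mode == "direct" and sigma is not None else {}),
                            **({"uwb_range_sigma_m": sigma} if mode == "solver" and sigma is not None else {}))
            # static tag: coarse internal step (one sample per fix) suffices
            t_grid = np.arange(0.0, duration_s + 0.5 * period_s, period_s)
            traj = Trajectory(tag, t_grid, np.tile([x, y], (len(t_grid), 1)),
                              step_s=period_s)
            fixes = synthesize_uwb_fixes(traj, layout, cfg, mode=mode)
            runs.append(StaticTagRun(pen, tag, np.array([x, y]), fixes))
    return runs
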