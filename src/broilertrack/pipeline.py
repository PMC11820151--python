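"""End-to-end seeded pipeline runs and file validation.

A run configuration (YAML/JSON) describes the pen, the number of tags,
the span and the seed; :func:`run_pipeline` executes
simulate -> activity -> spatial -> fusion -> trigger -> retention in
dependency order, writes every stage's CSV outputs under the output
directory, and records a manifest (config hash, seed, per-stage files
and row counts) so a re-run can be checked for byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from ._rng import rng_stream
from .activity import ActivityConfig, active_fraction, activity_mask, magnitude
from .fusion import (FusionConfig, TriggerConfig, movement_correlation,
                     motion_trigger_eval, resample_features)
from .layout import LightSchedule, MountOrientation, PenLayout
from .retention import (load_retention_fixture, records_from_frame,
                        summarize_retention, summary_frame)
from .simulate import (SimConfig, simulate_behavior, simulate_trajectory,
                       synthesize_imu, synthesize_uwb_fixes)
from .spatial import distance_walked, occupancy_histogram

log = logging.getLogger("broilertrack")

__all__ = ["RunManifest", "run_pipeline", "validate_files", "DEMO_CONFIG"]

DEMO_CONFIG: dict = {
    "seed": 42,
    "n_tags": 6,
    "duration_s": 86400,
    "pen": {"kind": "square", "side": 3.0},
    "uwb_period_s": 32,
    "imu_rate_hz": 20,
    "uwb_mode": "direct",
    "activity": {"threshold": 0.05, "baseline": "per_tag_mean",
                 "window_s": 1, "aggregation_s": 14400},
    "trigger": {"window_s": 1800, "distance_threshold_m": 5.0},
    "stages": ["simulate", "activity", "spatial", "fuse", "trigger", "retention"],
}

_STAGE_ORDER = ["simulate", "activity", "spatial", "fuse", "trigger", "retention"]
_STAGE_DEPS = {"activity": ["simulate"], "spatial": ["simulate"],
               "fuse": ["simulate"], "trigger": ["simulate"]}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)  # stage -> {files: {path: rows}}

    def to_json(self) -> str:
        return json.dumps({"config_hash": self.config_hash, "seed": self.seed,
                           "version": self.version, "stages": self.stages},
                          indent=2, sort_keys=True)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


def _validate_config(cfg: dict) -> dict:
    merged = {**DEMO_CONFIG, **cfg}
    checks = [
        ("seed", lambda v: isinstance(v, int) and v >= 0, "non-negative integer"),
        ("n_tags", lambda v: isinstance(v, int) and v > 0, "positive integer"),
        ("duration_s", lambda v: v > 0, "positive number"),
        ("uwb_period_s", lambda v: v > 0, "positive number"),
        ("imu_rate_hz", lambda v: v > 0, "positive number"),
        ("uwb_mode", lambda v: v in ("direct", "solver"), "'direct' or 'solver'"),
    ]
    for key, ok, desc in checks:
        if key not in merged or not ok(merged[key]):
            raise ValueError(f"config field {key!r} must be a {desc}, "
                             f"got {merged.get(key)!r}")
    unknown = [s for s in merged["stages"] if s not in _STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stages in config: {unknown}")
    return merged


def _pen_from_config(cfg: dict) -> PenLayout:
    pen = cfg.get("pen", {"kind": "square", "side": 3.0})
    if pen.get("kind") == "square":
        return PenLayout.square_pen(side=float(pen.get("side", 3.0)))
    if pen.get("kind") == "noise_test":
        return PenLayout.noise_test_pen()
    raise ValueError(f"config field 'pen.kind' must be 'square' or 'noise_test', got {pen.get('kind')!r}")


def run_pipeline(config: dict | str | Path, out_dir, seed: int | None = None) -> RunManifest:
    """Run the configured stages and write a manifest.

    Raises on the first stage error; the manifest is written only after
    every requested stage succeeded.
    """
    if not isinstance(config, dict):
        config = io.load_config(config)
    cfg = _validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest = RunManifest(cfg_hash, cfg["seed"], __version__)

    stages = [s for s in _STAGE_ORDER if s in cfg["stages"]]
    for s in stages:
        for dep in _STAGE_DEPS.get(s, []):
            if dep not in stages:
                raise ValueError(f"stage {s!r} requires missing upstream stage {dep!r}")

    layout = _pen_from_config(cfg)
    schedule = LightSchedule.broiler_16L8D()
    sim = SimConfig(seed=cfg["seed"], duration_s=float(cfg["duration_s"]),
                    uwb_period_s=float(cfg["uwb_period_s"]),
                    imu_rate_hz=float(cfg["imu_rate_hz"]))
    tags = [f"tag{i:03d}" for i in range(cfg["n_tags"])]

    def record(stage: str, path: Path, rows: int) -> None:
        manifest.stages.setdefault(stage, {"files": {}})
        manifest.stages[stage]["files"][path.name] = int(rows)

    traces, fixes_by_tag = {}, {}
    if "simulate" in stages:
        log.info("simulate: %d tags, %.0f s", len(tags), sim.duration_s)
        for tag in tags:
            beh = simulate_behavior(sim, schedule, tag_id=tag)
            traj = simulate_trajectory(beh, layout, sim)
            mount = MountOrientation.random(tag, rng_stream(sim.seed, tag, "mount"))
            imu = synthesize_imu(beh, mount, sim)
            fx = synthesize_uwb_fixes(traj, layout, sim, mode=cfg["uwb_mode"])
            traces[tag], fixes_by_tag[tag] = imu, fx
            record("simulate", io.write_trajectory(traj, out / f"trajectory_{tag}.csv"), len(traj.t))
            record("simulate", io.write_imu(imu, out / f"imu_{tag}.csv"), len(imu.t))
            record("simulate", io.write_fixes(fx, out / f"fixes_{tag}.csv"), len(fx))

    if "activity" in stages:
        acfg = cfg.get("activity", {})
        act_cfg = ActivityConfig(threshold=float(acfg.get("threshold", 0.05)),
                             baseline_mode=acfg.get("baseline", "per_tag_mean"),
                             window_s=float(acfg.get("window_s", 1)),
                             aggregation_s=float(acfg.get("aggregation_s", 14400)))
        rows = []
        for tag in tags:
            m = magnitude(traces[tag])
            summ = active_fraction(activity_mask(m, act_cfg), act_cfg,
                                   traces[tag].rate_hz, tag_id=tag,
                                   t_start=traces[tag].t[0])
            for rec in summ.intervals.itertuples():
                rows.append({"tag_id": tag, "t_start": rec.t_start,
                             "active_fraction": rec.active_fraction})
            rows.append({"tag_id": tag, "t_start": float("nan"),
                         "active_fraction": summ.overall_active_fraction})
        p = out / "activity_summary.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        record("activity", p, len(rows))

    if "spatial" in stages:
        grid = occupancy_histogram(list(fixes_by_tag.values()), layout)
        p = out / "occupancy_density.csv"
        np.savetxt(p, grid.density, delimiter=",")
        record("spatial", p, grid.density.shape[0])
        rows = []
        for tag in tags:
            if len(fixes_by_tag[tag]) < 2:
                continue
            ds = distance_walked(fixes_by_tag[tag],
                                 nominal_period_s=sim.uwb_period_s)
            d = ds.table.copy()
            d.insert(0, "tag_id", tag)
            rows.append(d)
        p = out / "distance_walked.csv"
        pd.concat(rows, ignore_index=True).to_csv(p, index=False)
        record("spatial", p, sum(len(r) for r in rows))

    if "fuse" in stages:
        rows = []
        for tag in tags:
            feats = resample_features(traces[tag], fixes_by_tag[tag], FusionConfig())
            corr = movement_correlation(feats)
            corr.insert(0, "tag_id", tag)
            rows.append(corr)
        p = out / "movement_correlation.csv"
        pd.concat(rows, ignore_index=True).to_csv(p, index=False)
        record("fuse", p, sum(len(r) for r in rows))

    if "trigger" in stages:
        tcfg = cfg.get("trigger", {})
        tc = TriggerConfig(window_s=float(tcfg.get("window_s", 1800)),
                           distance_threshold_m=float(tcfg.get("distance_threshold_m", 5.0)))
        rows = []
        for tag in tags:
            sweep = motion_trigger_eval(traces[tag], fixes_by_tag[tag], tc)
            sweep.insert(0, "tag_id", tag)
            rows.append(sweep)
        p = out / "trigger_sweep.csv"
        pd.concat(rows, ignore_index=True).to_csv(p, index=False)
        record("trigger", p, sum(len(r) for r in rows))

    if "retention" in stages:
        rec_path = cfg.get("retention_records")
        if rec_path:
            records = records_from_frame(pd.read_csv(rec_path))
        else:
            records = load_retention_fixture()
        summ = summary_frame(summarize_retention(records))
        p = out / "retention_summary.csv"
        summ.to_csv(p, index=False)
        record("retention", p, len(summ))

    manifest.write(out / "manifest.json")
    return manifest


@dataclass
class FileReport:
    path: str
    ok: bool
    issues: list


def validate_files(paths, pen_width: float = 3.0, pen_height: float = 3.0) -> list[FileReport]:
    """Schema and sanity checks for interchange CSVs.

    Checks the expected columns, strictly increasing timestamps (with the
    first offending line number), and value ranges: accelerations within
    +/- 16 g and positions within 10x the pen rectangle.
    """
    reports = []
    for path in paths:
        path = Path(path)
        issues: list[str] = []
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            reports.append(FileReport(str(path), False, [f"unreadable: {exc}"]))
            continue
        cols = set(df.columns)
        kind = None
        if {"ax_g", "ay_g", "az_g"} <= cols:
            kind = "imu"
        elif {"x_m", "y_m"} <= cols:
            kind = "fixes"
        elif {"method", "attach_day"} <= cols:
            kind = "retention"
        else:
            issues.append(f"unrecognized schema: columns {sorted(cols)}")
        if kind in ("imu", "fixes"):
            if "t_unix_s" not in cols:
                issues.append("missing column t_unix_s")
            else:
                t = df["t_unix_s"].to_numpy()
                bad = np.nonzero(np.diff(t) <= 0)[0]
                if bad.size:
                    issues.append(f"non-increasing timestamp at line {bad[0] + 3}")
        if kind == "imu":
            a = df[["ax_g", "ay_g", "az_g"]].to_numpy()
            if np.any(np.abs(a) > 16):
                issues.append("acceleration magnitude exceeds 16 g")
        if kind == "fixes":
            x, y = df["x_m"].to_numpy(), df["y_m"].to_numpy()
            if np.any(np.abs(x) > 10 * pen_width) or np.any(np.abs(y) > 10 * pen_height):
                issues.append("positions far outside the pen (>10x pen size)")
        reports.append(FileReport(str(path), not issues, issues))
    return reports
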