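"""Tidy CSV interchange for trajectories, IMU traces and fix series.

Column schemas (all timestamps are Unix seconds, UTC, float):

- trajectory: ``tag_id, t_unix_s, x_m, y_m``
- imu: ``tag_id, t_unix_s, ax_g, ay_g, az_g``
- fixes: ``tag_id, t_unix_s, x_m, y_m``
- retention records: ``bird_id, method, attach_day, detach_day, censored``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import ImuTrace, Trajectory
from .uwb import FixSeries

__all__ = [
    "write_trajectory", "read_trajectory",
    "write_imu", "read_imu",
    "write_fixes", "read_fixes",
    "load_config", "dump_config",
]

TRAJECTORY_COLUMNS = ["tag_id", "t_unix_s", "x_m", "y_m"]
IMU_COLUMNS = ["tag_id", "t_unix_s", "ax_g", "ay_g", "az_g"]
FIX_COLUMNS = ["tag_id", "t_unix_s", "x_m", "y_m"]


def write_trajectory(traj: Trajectory, path) -> Path:
    df = pd.DataFrame({"tag_id": traj.tag_id, "t_unix_s": traj.t,
                       "x_m": traj.xy[:, 0], "y_m": traj.xy[:, 1]})
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    t = df["t_unix_s"].to_numpy()
    step = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return Trajectory(df["tag_id"].iloc[0], t, df[["x_m", "y_m"]].to_numpy(),
                      step_s=step)


def write_imu(trace: ImuTrace, path) -> Path:
    df = pd.DataFrame({"tag_id": trace.tag_id, "t_unix_s": trace.t,
                       "ax_g": trace.samples[:, 0], "ay_g": trace.samples[:, 1],
                       "az_g": trace.samples[:, 2]})
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_imu(path, rate_hz: float | None = None) -> ImuTrace:
    df = pd.read_csv(path)
    t = df["t_unix_s"].to_numpy()
    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 20.0
    return ImuTrace(df["tag_id"].iloc[0], rate_hz, t,
                    df[["ax_g", "ay_g", "az_g"]].to_numpy())


def write_fixes(fixes: FixSeries, path) -> Path:
    path = Path(path)
    fixes.to_frame().to_csv(path, index=False)
    return path


def read_fixes(path) -> FixSeries:
    return FixSeries.from_frame(pd.read_csv(path))


def load_config(path) -> dict:
    """Load a YAML (or JSON, which is a YAML subset) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
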