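"""Shared fixtures: one simulated day of pen data reused across modules."""

import pytest

from broilertrack._rng import rng_stream
from broilertrack.layout import LightSchedule, MountOrientation, PenLayout
from broilertrack.simulate import (SimConfig, simulate_behavior,
                                   simulate_trajectory, synthesize_imu,
                                   synthesize_uwb_fixes)


@pytest.fixture(scope="session")
def schedule():
    return LightSchedule.broiler_16L8D()


@pytest.fixture(scope="session")
def pen():
    return PenLayout.square_pen()


@pytest.fixture(scope="session")
def day_config():
    return SimConfig(seed=11, duration_s=86400.0)


@pytest.fixture(scope="session")
def behavior_day(day_config, schedule):
    return simulate_behavior(day_config, schedule, tag_id="hen01")


@pytest.fixture(scope="session")
def trajectory_day(behavior_day, pen, day_config):
    return simulate_trajectory(behavior_day, pen, day_config)


@pytest.fixture(scope="session")
def imu_day(behavior_day, day_config):
    mount = MountOrientation.random("hen01", rng_stream(11, "hen01", "mount"))
    return synthesize_imu(behavior_day, mount, day_config)


@pytest.fixture(scope="session")
def fixes_day(trajectory_day, pen, day_config):
    return synthesize_uwb_fixes(trajectory_day, pen, day_config, mode="direct")
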