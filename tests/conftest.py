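"""Shared fixture helpers: building fixes and days at metric offsets."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from mobispace.trajectory import DayTrajectory, GpsFix, HomeLocation, Trajectory, unproject_local

TZ = timezone(timedelta(hours=2))
BASE = datetime(2023, 5, 1, 3, 0, tzinfo=TZ)  # Monday 3 AM
ORIGIN = HomeLocation(50.94, 6.96)


def fix_at(seconds: float, x_km: float = 0.0, y_km: float = 0.0, pid: str = "P0",
           origin: HomeLocation = ORIGIN, base: datetime = BASE) -> GpsFix:
    """A fix ``seconds`` after base time, at planar km offset from origin."""
    lat, lon = unproject_local(np.array([x_km, y_km]), origin)[0]
    return GpsFix(pid, base + timedelta(seconds=float(seconds)), float(lat), float(lon))


def day_from_points(points, pid: str = "P0", origin: HomeLocation = ORIGIN,
                    base: datetime = BASE) -> DayTrajectory:
    """A DayTrajectory from (seconds, x_km, y_km) triples."""
    fixes = [fix_at(s, x, y, pid, origin, base) for s, x, y in points]
    return DayTrajectory(base.date(), fixes)


def traj_from_points(points, pid: str = "P0", origin: HomeLocation = ORIGIN,
                     base: datetime = BASE) -> Trajectory:
    return Trajectory(pid, [fix_at(s, x, y, pid, origin, base) for s, x, y in points])


@pytest.fixture
def origin() -> HomeLocation:
    return ORIGIN
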