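"""GPS data model and trajectory preprocessing.

A *fix* is one GPS observation (WGS84 coordinates plus a timezone-aware
timestamp). Trajectories are per-participant, time-ordered fix sequences.
Preprocessing covers speed-based outlier removal, splitting weeks into
logical days at a 3 AM boundary, and a local planar projection used for
all area/variance geometry downstream.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GpsFix",
    "Trajectory",
    "DayTrajectory",
    "HomeLocation",
    "haversine_km",
    "bearing_rad",
    "read_fixes",
    "write_day_fixes",
    "remove_outliers",
    "split_days",
    "project_local",
    "unproject_local",
]


@dataclass(frozen=True, slots=True)
class GpsFix:
    """One GPS observation: coordinates and a timezone-aware timestamp."""

    participant_id: str
    timestamp: datetime
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")
        if self.timestamp.tzinfo is None:
            raise ValueError("timestamp must be timezone-aware")


@dataclass
class Trajectory:
    """Time-ordered fixes of one participant."""

    participant_id: str
    fixes: list[GpsFix]

    def __post_init__(self) -> None:
        for a, b in zip(self.fixes, self.fixes[1:]):
            if b.timestamp < a.timestamp:
                raise ValueError("fixes must be time-ordered")
        for f in self.fixes:
            if f.participant_id != self.participant_id:
                raise ValueError("all fixes must share the trajectory's participant id")

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class DayTrajectory:
    """Fixes of one logical day (3 AM to next-day 3 AM window)."""

    logical_date: date
    fixes: list[GpsFix]

    @property
    def weekend(self) -> bool:
        return self.logical_date.weekday() >= 5

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass(frozen=True)
class HomeLocation:
    """A participant's home coordinate and its provenance."""

    lat: float
    lon: float
    source: str = "address"  # "address" or "gps"

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0 or not -180.0 <= self.lon <= 180.0:
            raise ValueError("invalid home coordinates")
        if self.source not in ("address", "gps"):
            raise ValueError(f"unknown home source: {self.source}")


class RecordError(ValueError):
    """A malformed input record, carrying the offending line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


# ---------------------------------------------------------------------------
# geodesy


def haversine_km(lat1, lon1, lat2=None, lon2=None) -> np.ndarray | float:
    """Great-circle distance in km (spherical earth, R = 6371 km).

    Accepts either four scalar/array coordinate arguments or two
    :class:`GpsFix` objects.
    """
    if isinstance(lat1, GpsFix):
        a, b = lat1, lon1
        lat1, lon1, lat2, lon2 = a.lat, a.lon, b.lat, b.lon
    p1, l1, p2, l2 = (np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlmb = l2 - l1
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def bearing_rad(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Initial geodesic bearing from point 1 to point 2, in [0, 2*pi).

    0 = due north, pi/2 = due east (compass convention).
    """
    p1, l1, p2, l2 = (np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    dlmb = l2 - l1
    y = np.sin(dlmb) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlmb)
    theta = np.mod(np.arctan2(y, x), 2.0 * np.pi)
    return float(theta) if theta.ndim == 0 else theta


def project_local(
    fixes: Sequence[GpsFix] | np.ndarray, origin: HomeLocation | tuple[float, float]
) -> np.ndarray:
    """Project fixes to planar km east/north via an azimuthal-equidistant map.

    Centered at ``origin``; distances from the origin are preserved exactly,
    which keeps home-centred indicators free of projection error.

    Accepts a sequence of fixes or an (n, 2) lat/lon array; returns (n, 2)
    columns (x east, y north) in km.
    """
    if isinstance(origin, HomeLocation):
        lat0, lon0 = origin.lat, origin.lon
    else:
        lat0, lon0 = origin
    arr = _latlon_array(fixes)
    if arr.size == 0:
        return np.empty((0, 2))
    d = haversine_km(lat0, lon0, arr[:, 0], arr[:, 1])
    theta = bearing_rad(lat0, lon0, arr[:, 0], arr[:, 1])
    d = np.atleast_1d(d)
    theta = np.atleast_1d(theta)
    return np.column_stack([d * np.sin(theta), d * np.cos(theta)])


def unproject_local(
    xy: np.ndarray, origin: HomeLocation | tuple[float, float]
) -> np.ndarray:
    """Inverse of :func:`project_local`: planar km back to (lat, lon) degrees."""
    if isinstance(origin, HomeLocation):
        lat0, lon0 = origin.lat, origin.lon
    else:
        lat0, lon0 = origin
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    phi1 = math.radians(lat0)
    lmb1 = math.radians(lon0)
    r = np.hypot(xy[:, 0], xy[:, 1])
    c = r / EARTH_RADIUS_KM
    alpha = np.arctan2(xy[:, 0], xy[:, 1])
    sin_c, cos_c = np.sin(c), np.cos(c)
    phi2 = np.arcsin(
        np.clip(math.sin(phi1) * cos_c + math.cos(phi1) * sin_c * np.cos(alpha), -1, 1)
    )
    lmb2 = lmb1 + np.arctan2(
        np.sin(alpha) * sin_c * math.cos(phi1), cos_c - math.sin(phi1) * np.sin(phi2)
    )
    out = np.column_stack([np.degrees(phi2), np.degrees(lmb2)])
    # exact at the origin where the azimuth is undefined
    out[r == 0.0] = (lat0, lon0)
    return out


def _latlon_array(fixes) -> np.ndarray:
    if isinstance(fixes, np.ndarray):
        return np.atleast_2d(fixes.astype(float))
    return np.array([(f.lat, f.lon) for f in fixes], dtype=float).reshape(-1, 2)


def fix_times_seconds(fixes: Sequence[GpsFix]) -> np.ndarray:
    """Timestamps as epoch seconds (float), vectorised helper."""
    return np.array([f.timestamp.timestamp() for f in fixes], dtype=float)


# ---------------------------------------------------------------------------
# readers / writers


def read_fixes(path: str | Path, format: str = "csv") -> list[Trajectory]:
    """Read GPS fixes into one Trajectory per participant.

    CSV dialect: header ``participant_id,timestamp,lat,lon`` with ISO-8601
    timestamps carrying a UTC offset. GPX 1.1 track points are also accepted
    (one participant per file, id = file stem). Duplicate
    (participant, timestamp) rows collapse to the first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        rows = _read_csv_rows(path)
    elif format == "gpx":
        rows = _read_gpx_rows(path)
    else:
        raise ValueError(f"unknown format: {format!r}")

    by_pid: dict[str, dict[datetime, GpsFix]] = {}
    for pid, ts, lat, lon in rows:
        bucket = by_pid.setdefault(pid, {})
        if ts not in bucket:  # first occurrence wins
            bucket[ts] = GpsFix(pid, ts, lat, lon)
    return [
        Trajectory(pid, [bucket[t] for t in sorted(bucket)])
        for pid, bucket in sorted(by_pid.items())
    ]


def _read_csv_rows(path: Path):
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except pd.errors.EmptyDataError:
        return
    required = {"participant_id", "timestamp", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ts = datetime.fromisoformat(str(row.timestamp))
            if ts.tzinfo is None:
                raise ValueError("timestamp lacks a UTC offset")
            lat, lon = float(row.lat), float(row.lon)
            yield str(row.participant_id), ts, lat, lon
        except (ValueError, TypeError) as exc:
            raise RecordError(i, str(exc)) from exc


_GPX_NS = "{http://www.topografix.com/GPX/1/1}"


def _read_gpx_rows(path: Path):
    root = ET.parse(path).getroot()
    pid = path.stem
    for i, pt in enumerate(root.iter(f"{_GPX_NS}trkpt"), start=1):
        t = pt.find(f"{_GPX_NS}time")
        if t is None or t.text is None:
            raise RecordError(i, "track point without <time>")
        ts = datetime.fromisoformat(t.text.replace("Z", "+00:00"))
        yield pid, ts, float(pt.get("lat")), float(pt.get("lon"))


def write_day_fixes(days: Iterable[DayTrajectory], path: str | Path) -> None:
    """Write cleaned per-day fixes: the input CSV dialect plus logical_date."""
    records = [
        {
            "participant_id": f.participant_id,
            "timestamp": f.timestamp.isoformat(),
            "lat": f.lat,
            "lon": f.lon,
            "logical_date": d.logical_date.isoformat(),
        }
        for d in days
        for f in d.fixes
    ]
    pd.DataFrame(
        records, columns=["participant_id", "timestamp", "lat", "lon", "logical_date"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing


def remove_outliers(traj: Trajectory, max_speed_kmh: float = 330.0) -> Trajectory:
    """Drop fixes implying an unrealistic travel speed.

    Scans in time order; each fix's speed is computed against the previous
    *retained* fix, so one spike cannot invalidate the true fix after it.
    The default 330 km/h is the top speed of German high-speed rail — the
    fastest plausible ground travel for the cohort. Zero time difference
    counts as infinite speed and drops the later fix. Idempotent.
    """
    if len(traj.fixes) <= 1:
        return Trajectory(traj.participant_id, list(traj.fixes))
    kept = [traj.fixes[0]]
    for fx in traj.fixes[1:]:
        prev = kept[-1]
        dt_h = (fx.timestamp - prev.timestamp).total_seconds() / 3600.0
        if dt_h <= 0.0:
            continue
        if haversine_km(prev, fx) / dt_h > max_speed_kmh:
            continue
        kept.append(fx)
    return Trajectory(traj.participant_id, kept)


def split_days(traj: Trajectory, boundary: time = time(3, 0)) -> list[DayTrajectory]:
    """Split a trajectory into logical days at the boundary hour (default 3 AM).

    A logical day runs [boundary, next-day boundary); a fix at exactly the
    boundary starts the new day. Splitting at 3 AM instead of midnight keeps
    late-evening activity in one piece. Days with no fixes produce no entry.
    """
    offset = timedelta(hours=boundary.hour, minutes=boundary.minute)
    buckets: dict[date, list[GpsFix]] = {}
    for fx in traj.fixes:
        logical = (fx.timestamp - offset).date()
        buckets.setdefault(logical, []).append(fx)
    return [DayTrajectory(d, buckets[d]) for d in sorted(buckets)]
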