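"""Stop/move segmentation and annotation of GPS days.

A *stop* is a dwell of at least 5 minutes inside a bounded region
(roaming radius 150 m from the first fix of the candidate, following the
time-based clustering of Montoliu-style significant-place detection);
a *move* is a run of fixes between stops lasting more than 3 minutes; a
*jump* is a fix that exits a stop region after a data gap of more than an
hour (typically the first fix after in-building signal loss).

Moves are classified *active* (non-motorised) vs *passive* (motorised) by
their 90th-percentile fix-pair speed at 25 km/h. Stops are flagged
out-of-home against a 150 m home buffer, and clustered across days
(DBSCAN, 60 m, two stops) to identify multiply-visited places.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .trajectory import (
    EARTH_RADIUS_KM,
    DayTrajectory,
    GpsFix,
    HomeLocation,
    fix_times_seconds,
    haversine_km,
)

__all__ = [
    "StopSegment",
    "MoveSegment",
    "SegmentedDay",
    "detect_stops",
    "extract_moves",
    "merge_stops",
    "classify_mode",
    "detect_home",
    "annotate_oh",
    "cluster_stops",
    "segment_day",
]

MODE_SPEED_THRESHOLD_KMH = 25.0


@dataclass
class StopSegment:
    """A dwell at one place: median-coordinate centre plus arrival/departure."""

    center_lat: float
    center_lon: float
    arrival: datetime
    departure: datetime
    member_fixes: list[GpsFix]
    is_out_of_home: bool | None = None
    cluster_id: int | None = None
    multiply_visited: bool = False

    @property
    def center(self) -> tuple[float, float]:
        return (self.center_lat, self.center_lon)

    @property
    def duration_min(self) -> float:
        return (self.departure - self.arrival).total_seconds() / 60.0


@dataclass
class MoveSegment:
    """Travel between stops: path, 90th-percentile speed, transport mode."""

    member_fixes: list[GpsFix]
    start: datetime
    end: datetime
    path_length_km: float
    p90_speed_kmh: float
    mode: str  # "active" or "passive"
    speed_undefined: bool = False  # < 2 fixes: no pair speed, defaulted active

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass
class SegmentedDay:
    """One logical day split into stops, moves and jump fixes."""

    day: DayTrajectory
    stops: list[StopSegment]
    moves: list[MoveSegment]
    jump_fixes: list[GpsFix]
    fix_oh: np.ndarray | None = None  # per-fix out-of-home flags, set by annotate_oh


def _make_stop(members: list[GpsFix]) -> StopSegment:
    lat = float(np.median([f.lat for f in members]))
    lon = float(np.median([f.lon for f in members]))
    return StopSegment(lat, lon, members[0].timestamp, members[-1].timestamp, list(members))


def detect_stops(
    day: DayTrajectory,
    roam_m: float = 150.0,
    min_stop_min: float = 5.0,
    intra_gap_min: float = 60.0,
) -> tuple[list[StopSegment], list[GpsFix], list[GpsFix]]:
    """Detect stops in one day; returns (stops, residual fixes, jump fixes).

    Grows a candidate from an anchor fix, adding successive fixes while
    they stay within ``roam_m`` of the anchor. When a fix exits the region
    the candidate is emitted as a stop if its time span reaches
    ``min_stop_min``; otherwise the anchor fix is released as residual and
    the anchor advances by one fix (time-based clustering semantics, which
    keeps a candidate anchored on a transitional fix from delaying the next
    true stop). An internal time gap longer than ``intra_gap_min`` ends the
    candidate at the gap so the dwell before and after it form two separate
    stops; a fix that *exits* the region after such a gap is labelled a
    jump.
    """
    fixes = day.fixes
    n = len(fixes)
    if n == 0:
        return [], [], []
    lats = np.array([f.lat for f in fixes])
    lons = np.array([f.lon for f in fixes])
    t = fix_times_seconds(fixes)
    roam_km = roam_m / 1000.0
    min_stop_s = min_stop_min * 60.0
    gap_s = intra_gap_min * 60.0

    stops: list[StopSegment] = []
    residual: list[GpsFix] = []
    jumps: list[GpsFix] = []

    i = 0
    while i < n:
        d = np.atleast_1d(haversine_km(lats[i], lons[i], lats[i + 1 :], lons[i + 1 :]))
        exits = np.nonzero(d > roam_km)[0]
        j = (i + 1 + exits[0]) if exits.size else n  # first fix outside the region

        # truncate the candidate at the first internal gap > intra_gap:
        # the dwell after the gap forms a separate stop
        gaps = np.nonzero(np.diff(t[i:j]) > gap_s)[0]
        end = (i + 1 + gaps[0]) if gaps.size else j  # one past the last member

        if t[end - 1] - t[i] >= min_stop_s:
            stops.append(_make_stop(fixes[i:end]))
            if end < j:
                i = end  # fix after the gap, still inside the region
            elif j < n and t[j] - t[j - 1] > gap_s:
                jumps.append(fixes[j])  # exits the region after a long gap
                i = j + 1
            else:
                i = j
        else:
            residual.append(fixes[i])  # advance the anchor by one fix
            i += 1
    return stops, residual, jumps


def extract_moves(
    day: DayTrajectory,
    stops: Sequence[StopSegment],
    jumps: Sequence[GpsFix] = (),
    min_move_min: float = 3.0,
) -> tuple[list[MoveSegment], list[list[GpsFix]]]:
    """Extract moves between stops; returns (moves, residue runs).

    Maximal runs of fixes assigned to no stop and not labelled jump become
    moves when their time span exceeds ``min_move_min``; shorter runs are
    returned as residue (candidates for stop merging).
    """
    stop_members = {id(f) for s in stops for f in s.member_fixes}
    jump_ids = {id(f) for f in jumps}
    runs: list[list[GpsFix]] = []
    current: list[GpsFix] = []
    for f in day.fixes:
        if id(f) in stop_members or id(f) in jump_ids:
            if current:
                runs.append(current)
                current = []
        else:
            current.append(f)
    if current:
        runs.append(current)

    moves, residue = [], []
    for run in runs:
        span_min = (run[-1].timestamp - run[0].timestamp).total_seconds() / 60.0
        if span_min > min_move_min:
            moves.append(_make_move(run))
        else:
            residue.append(run)
    return moves, residue


def _pair_speeds_kmh(fixes: Sequence[GpsFix]) -> np.ndarray:
    if len(fixes) < 2:
        return np.empty(0)
    lats = np.array([f.lat for f in fixes])
    lons = np.array([f.lon for f in fixes])
    t = fix_times_seconds(fixes)
    d = haversine_km(lats[:-1], lons[:-1], lats[1:], lons[1:])
    dt_h = np.diff(t) / 3600.0
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(dt_h > 0, np.atleast_1d(d) / dt_h, np.inf)
    return v


def _make_move(run: list[GpsFix]) -> MoveSegment:
    speeds = _pair_speeds_kmh(run)
    length = float(
        np.sum(
            haversine_km(
                np.array([f.lat for f in run[:-1]]),
                np.array([f.lon for f in run[:-1]]),
                np.array([f.lat for f in run[1:]]),
                np.array([f.lon for f in run[1:]]),
            )
        )
        if len(run) >= 2
        else 0.0
    )
    move = MoveSegment(
        member_fixes=list(run),
        start=run[0].timestamp,
        end=run[-1].timestamp,
        path_length_km=length,
        p90_speed_kmh=float(np.percentile(speeds, 90)) if speeds.size else float("nan"),
        mode="active",
        speed_undefined=speeds.size == 0,
    )
    return classify_mode(move)


def classify_mode(move: MoveSegment, threshold_kmh: float = MODE_SPEED_THRESHOLD_KMH) -> MoveSegment:
    """Set the transport mode from the move's 90th-percentile pair speed.

    p90 speed >= 25 km/h -> passive (motorised), below -> active. Moves with
    fewer than two fixes have no defined speed and default to active with
    ``speed_undefined`` set.
    """
    if move.speed_undefined or np.isnan(move.p90_speed_kmh):
        move.mode = "active"
        move.speed_undefined = True
    else:
        move.mode = "passive" if move.p90_speed_kmh >= threshold_kmh else "active"
    return move


def merge_stops(
    stops: list[StopSegment],
    moves: Sequence[MoveSegment] = (),
    jumps: Sequence[GpsFix] = (),
    max_between_min: float = 3.0,
    dist_m: float = 150.0,
    max_dt_min: float = 60.0,
) -> list[StopSegment]:
    """Merge consecutive stops interrupted only by short non-move residue.

    Adjacent stops are fused when nothing but residue (runs <= 3 min that
    did not qualify as moves) lies between them, their centres are closer
    than ``dist_m`` and the inter-stop interval is shorter than
    ``max_dt_min``. Fusion unions the member fixes, recomputes the median
    centre and keeps the first arrival / second departure; the scan repeats
    left-to-right until a fixpoint.
    """
    stops = sorted(stops, key=lambda s: s.arrival)
    move_windows = [(m.start, m.end) for m in moves]
    jump_times = [f.timestamp for f in jumps]

    def blocked(a: StopSegment, b: StopSegment) -> bool:
        for s, e in move_windows:
            if s >= a.departure and e <= b.arrival:
                return True
        return any(a.departure < jt < b.arrival for jt in jump_times)

    changed = True
    while changed:
        changed = False
        out: list[StopSegment] = []
        k = 0
        while k < len(stops):
            if k + 1 < len(stops):
                a, b = stops[k], stops[k + 1]
                gap_min = (b.arrival - a.departure).total_seconds() / 60.0
                close = (
                    haversine_km(a.center_lat, a.center_lon, b.center_lat, b.center_lon) * 1000.0
                    < dist_m
                )
                # any fix run > max_between_min between two stops is a move
                # and therefore blocks the merge
                if not blocked(a, b) and gap_min < max_dt_min and close:
                    out.append(_make_stop(a.member_fixes + b.member_fixes))
                    k += 2
                    changed = True
                    continue
            out.append(stops[k])
            k += 1
        stops = out
    return stops


def _dbscan_haversine(lats: np.ndarray, lons: np.ndarray, eps_m: float, min_pts: int) -> np.ndarray:
    pts = np.radians(np.column_stack([lats, lons]))
    eps = eps_m / 1000.0 / EARTH_RADIUS_KM
    return DBSCAN(eps=eps, min_samples=min_pts, metric="haversine", algorithm="ball_tree").fit(pts).labels_


def detect_home(
    valid_days: Sequence[DayTrajectory],
    address_home: HomeLocation | None = None,
    eps_m: float = 60.0,
    min_pts: int = 3,
    buffer_m: float = 60.0,
    min_improvement: float = 0.01,
) -> HomeLocation:
    """Detect the GPS-based home from first/last fixes of valid days.

    DBSCAN (60 m, 3 fixes) over the set of first-morning and last-evening
    fixes of every valid day; the candidate is the cluster centroid closest
    to the address home (largest cluster when no address). The GPS home
    replaces the address only when it captures more than 1 % more of all
    retained fixes within a 60 m buffer than the address does.
    """
    if not valid_days:
        raise ValueError("home undeterminable: no valid days")
    boundary = [d.fixes[0] for d in valid_days] + [d.fixes[-1] for d in valid_days if len(d) > 1]
    lats = np.array([f.lat for f in boundary])
    lons = np.array([f.lon for f in boundary])
    labels = _dbscan_haversine(lats, lons, eps_m, min_pts)

    candidates: list[tuple[float, float, int]] = []
    for lbl in sorted(set(labels) - {-1}):
        m = labels == lbl
        candidates.append((float(lats[m].mean()), float(lons[m].mean()), int(m.sum())))

    if not candidates:
        if address_home is not None:
            return address_home
        raise ValueError("home undeterminable: no boundary-fix cluster and no address")

    if address_home is not None:
        gps_lat, gps_lon, _ = min(
            candidates, key=lambda c: haversine_km(c[0], c[1], address_home.lat, address_home.lon)
        )
    else:
        gps_lat, gps_lon, _ = max(candidates, key=lambda c: c[2])
        return HomeLocation(gps_lat, gps_lon, source="gps")

    all_lat = np.concatenate([[f.lat for f in d.fixes] for d in valid_days])
    all_lon = np.concatenate([[f.lon for f in d.fixes] for d in valid_days])
    buf_km = buffer_m / 1000.0
    share_gps = float(np.mean(haversine_km(gps_lat, gps_lon, all_lat, all_lon) <= buf_km))
    share_addr = float(
        np.mean(haversine_km(address_home.lat, address_home.lon, all_lat, all_lon) <= buf_km)
    )
    if share_gps - share_addr > min_improvement:
        return HomeLocation(gps_lat, gps_lon, source="gps")
    return address_home


def annotate_oh(
    segday: SegmentedDay, home: HomeLocation, buffer_m: float = 150.0
) -> SegmentedDay:
    """Flag fixes and stops as out-of-home beyond a buffer around home.

    A fix or stop centre exactly on the buffer boundary counts as at home
    (closed buffer).
    """
    buf_km = buffer_m / 1000.0
    if segday.day.fixes:
        lats = np.array([f.lat for f in segday.day.fixes])
        lons = np.array([f.lon for f in segday.day.fixes])
        segday.fix_oh = np.atleast_1d(haversine_km(home.lat, home.lon, lats, lons)) > buf_km
    else:
        segday.fix_oh = np.zeros(0, dtype=bool)
    for s in segday.stops:
        s.is_out_of_home = bool(
            haversine_km(home.lat, home.lon, s.center_lat, s.center_lon) > buf_km
        )
    return segday


def cluster_stops(
    stops: Sequence[StopSegment], eps_m: float = 60.0, min_pts: int = 2
) -> list[StopSegment]:
    """Cluster stop centres across days to mark multiply-visited places.

    DBSCAN over centres (60 m, minimum two stops); clustered stops share a
    cluster id and are flagged multiply visited, noise stops get singleton
    ids. Mutates and returns the input stops.
    """
    stops = list(stops)
    if not stops:
        return stops
    lats = np.array([s.center_lat for s in stops])
    lons = np.array([s.center_lon for s in stops])
    labels = _dbscan_haversine(lats, lons, eps_m, min_pts)
    next_id = int(labels.max()) + 1 if (labels != -1).any() else 0
    for s, lbl in zip(stops, labels):
        if lbl == -1:
            s.cluster_id = next_id
            s.multiply_visited = False
            next_id += 1
        else:
            s.cluster_id = int(lbl)
            s.multiply_visited = True
    return stops


def segment_day(
    day: DayTrajectory,
    home: HomeLocation | None = None,
    roam_m: float = 150.0,
    min_stop_min: float = 5.0,
    intra_gap_min: float = 60.0,
    min_move_min: float = 3.0,
    merge_dist_m: float = 150.0,
    merge_dt_min: float = 60.0,
    home_buffer_m: float = 150.0,
) -> SegmentedDay:
    """Full per-day segmentation: detect, extract moves, merge, annotate."""
    stops, _, jumps = detect_stops(day, roam_m, min_stop_min, intra_gap_min)
    moves, _ = extract_moves(day, stops, jumps, min_move_min)
    stops = merge_stops(stops, moves, jumps, min_move_min, merge_dist_m, merge_dt_min)
    segday = SegmentedDay(day=day, stops=stops, moves=moves, jump_fixes=jumps)
    if home is not None:
        annotate_oh(segday, home, home_buffer_m)
    return segday
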