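"""The 20 daily mobility indicators and their weekly aggregation.

Life-space geometry (convex hull, standard deviational ellipse, Gravelius
compactness), durations (time out of home, transport-mode durations),
counts (locations visited), stop-location entropy, day-to-day life-space
overlap, circular statistics of the direction of the farthest point from
home, and timing of out-of-home activity.

All planar geometry runs on azimuthal-equidistant km coordinates centred
at the participant's home (see :func:`mobispace.trajectory.project_local`).
Daily values aggregate to weekly values by the median, except the
direction of the farthest point (circular standard deviation across days)
and the activity-timing code (mean). Each indicator is computed on its
day-selection scheme: R (random valid days) or M (valid days containing at
least one move).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import LineString, MultiPoint, Polygon
from shapely.ops import unary_union

from .segmentation import MoveSegment, SegmentedDay, StopSegment
from .trajectory import GpsFix, HomeLocation, bearing_rad, fix_times_seconds, haversine_km, project_local

__all__ = [
    "INDICATOR_NAMES",
    "DAY_SELECTION_SCHEME",
    "INDICATOR_TAXONOMY",
    "HullResult",
    "SdeResult",
    "max_dist",
    "convex_hull",
    "sde",
    "loc_var",
    "trip_indicators",
    "toh",
    "entropy",
    "num_loc",
    "num_uniq_loc",
    "revisited_ls",
    "bearing_max_dist",
    "circular_sd",
    "grav_compact",
    "maj2min",
    "timing_indicators",
    "compute_daily_indicators",
    "aggregate_week",
]

LOCVAR_EPS_KM2 = 1e-6

INDICATOR_NAMES: tuple[str, ...] = (
    "MaxDist",
    "CHull",
    "SDE",
    "LengthPerTrip",
    "LocVar",
    "DurPTM",
    "TOH",
    "Entropy",
    "NumLoc",
    "NumUniqLoc",
    "DurATM",
    "MaxDurATM",
    "RevisitedLS",
    "AvgRevisitedLS",
    "SDDirMaxDist",
    "GravCompact",
    "Maj2MinAxis",
    "TimeMaxDist",
    "TimeFirstMove",
    "TimePeriodActive",
)

#: Day-selection scheme per indicator: R = random valid days,
#: M = valid days containing at least one move.
DAY_SELECTION_SCHEME: dict[str, str] = {
    "MaxDist": "R",
    "CHull": "R",
    "SDE": "R",
    "LengthPerTrip": "M",
    "LocVar": "R",
    "DurPTM": "R",
    "TOH": "R",
    "Entropy": "R",
    "NumLoc": "R",
    "NumUniqLoc": "M",
    "DurATM": "R",
    "MaxDurATM": "R",
    "RevisitedLS": "M",
    "AvgRevisitedLS": "M",
    "SDDirMaxDist": "M",
    "GravCompact": "M",
    "Maj2MinAxis": "M",
    "TimeMaxDist": "M",
    "TimeFirstMove": "M",
    "TimePeriodActive": "M",
}

#: Classification tags: movement scope (trajectory/stop/move), the
#: characteristic aspect measured, attribute qualifier, the statistical
#: property of the weekly aggregate, and the temporal scale.
INDICATOR_TAXONOMY: dict[str, dict[str, str]] = {
    "MaxDist": dict(scope="trajectory", characteristic="space_extent", property="maximum"),
    "CHull": dict(scope="trajectory", characteristic="space_extent", property="central_tendency"),
    "SDE": dict(scope="trajectory", characteristic="space_extent", property="central_tendency"),
    "LengthPerTrip": dict(scope="move", characteristic="space_extent", property="central_tendency"),
    "LocVar": dict(scope="trajectory", characteristic="space_distribution", property="variability"),
    "DurPTM": dict(scope="move", characteristic="time_duration", attribute="passive_transport", property="central_tendency"),
    "TOH": dict(scope="trajectory", characteristic="time_duration", property="central_tendency"),
    "Entropy": dict(scope="stop", characteristic="temporal_distribution", property="variability"),
    "NumLoc": dict(scope="stop", characteristic="count", property="central_tendency"),
    "NumUniqLoc": dict(scope="stop", characteristic="count", property="central_tendency"),
    "DurATM": dict(scope="move", characteristic="time_duration", attribute="active_transport", property="central_tendency"),
    "MaxDurATM": dict(scope="move", characteristic="time_duration", attribute="active_transport", property="maximum"),
    "RevisitedLS": dict(scope="trajectory", characteristic="space_distribution", property="central_tendency"),
    "AvgRevisitedLS": dict(scope="trajectory", characteristic="space_distribution", property="central_tendency"),
    "SDDirMaxDist": dict(scope="trajectory", characteristic="space_distribution", property="variability"),
    "GravCompact": dict(scope="trajectory", characteristic="space_shape", property="central_tendency"),
    "Maj2MinAxis": dict(scope="trajectory", characteristic="space_shape", property="central_tendency"),
    "TimeMaxDist": dict(scope="trajectory", characteristic="time_timing", property="central_tendency"),
    "TimeFirstMove": dict(scope="move", characteristic="time_timing", property="central_tendency"),
    "TimePeriodActive": dict(scope="trajectory", characteristic="temporal_distribution", property="central_tendency"),
}
assert set(INDICATOR_TAXONOMY) == set(INDICATOR_NAMES)

for _name, _tags in INDICATOR_TAXONOMY.items():
    _tags.setdefault("attribute", "none")
    _tags["temporal_scale"] = "global"
    _tags["day_selection"] = DAY_SELECTION_SCHEME[_name]


@dataclass(frozen=True)
class HullResult:
    """Convex hull of the day's projected fixes (planar km)."""

    polygon: Polygon | None
    area_km2: float
    perimeter_km: float


@dataclass(frozen=True)
class SdeResult:
    """Standard deviational ellipse: 1-SD semi-axes of the point cloud."""

    center: tuple[float, float]
    semi_major_km: float
    semi_minor_km: float
    orientation_rad: float
    area_km2: float


# ---------------------------------------------------------------------------
# per-day geometry


def max_dist(fixes: Sequence[GpsFix], home: HomeLocation) -> float | None:
    """Distance (km) from home to the GPS fix farthest away from home."""
    if not fixes:
        return None
    lats = np.array([f.lat for f in fixes])
    lons = np.array([f.lon for f in fixes])
    return float(np.max(np.atleast_1d(haversine_km(home.lat, home.lon, lats, lons))))


def convex_hull(xy: np.ndarray) -> HullResult:
    """Convex hull of projected points; degenerate inputs give zero area."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    uniq = np.unique(xy, axis=0)
    if len(uniq) == 1:
        return HullResult(None, 0.0, 0.0)
    hull = MultiPoint(uniq).convex_hull
    if isinstance(hull, Polygon):
        return HullResult(hull, float(hull.area), float(hull.length))
    # collinear: shapely returns a LineString; perimeter = out-and-back
    length = float(hull.length) if isinstance(hull, LineString) else 0.0
    return HullResult(None, 0.0, 2.0 * length)


def sde(xy: np.ndarray) -> SdeResult | None:
    """Standard deviational ellipse of projected points.

    Centre = mean point; orientation = principal axis of the sample
    covariance; semi-axes = the standard deviations along the principal
    directions (1 SD, no sqrt(2) inflation); area = pi * s1 * s2. Fewer
    than three points, or a collinear cloud, has no ellipse (None).
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if len(xy) < 3:
        return None
    center = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= max(1e-12, 1e-10 * evals[1]):
        return None  # collinear
    semi_minor, semi_major = math.sqrt(evals[0]), math.sqrt(evals[1])
    major_vec = evecs[:, 1]
    orientation = math.atan2(major_vec[1], major_vec[0]) % math.pi
    return SdeResult(
        center=(float(center[0]), float(center[1])),
        semi_major_km=semi_major,
        semi_minor_km=semi_minor,
        orientation_rad=orientation,
        area_km2=math.pi * semi_major * semi_minor,
    )


def loc_var(xy: np.ndarray, eps: float = LOCVAR_EPS_KM2) -> float | None:
    """Location variance: ln of the summed planar coordinate variances (km^2)."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if len(xy) < 2:
        return None
    v = float(np.var(xy[:, 0], ddof=1) + np.var(xy[:, 1], ddof=1))
    return math.log(v + eps)


def grav_compact(hull: HullResult) -> float | None:
    """Gravelius compactness K = P / (2 sqrt(pi A)); 1 for a circle."""
    if hull.area_km2 <= 0.0:
        return None
    return hull.perimeter_km / (2.0 * math.sqrt(math.pi * hull.area_km2))


def maj2min(ellipse: SdeResult | None) -> float | None:
    """Elongation: ratio of the SDE's major to minor semi-axis (>= 1)."""
    if ellipse is None or ellipse.semi_minor_km <= 0.0:
        return None
    return ellipse.semi_major_km / ellipse.semi_minor_km


# ---------------------------------------------------------------------------
# durations, counts, entropy


def trip_indicators(moves: Sequence[MoveSegment]) -> dict[str, float | None]:
    """LengthPerTrip (km), DurPTM/DurATM/MaxDurATM (min) from a day's moves."""
    if not moves:
        return {"LengthPerTrip": None, "DurPTM": 0.0, "DurATM": 0.0, "MaxDurATM": 0.0}
    active = [m for m in moves if m.mode == "active"]
    passive = [m for m in moves if m.mode == "passive"]
    return {
        "LengthPerTrip": float(np.mean([m.path_length_km for m in moves])),
        "DurPTM": float(sum(m.duration_min for m in passive)),
        "DurATM": float(sum(m.duration_min for m in active)),
        "MaxDurATM": float(max((m.duration_min for m in active), default=0.0)),
    }


def toh(fixes: Sequence[GpsFix], oh_flags: np.ndarray, max_gap_min: float = 60.0) -> float:
    """Time out of home in minutes.

    Sums the time between consecutive fixes when both are out of home and
    the gap does not exceed ``max_gap_min`` (interpolating across short
    in-building signal gaps, not across long ones).
    """
    if len(fixes) < 2:
        return 0.0
    t = fix_times_seconds(fixes)
    dt_min = np.diff(t) / 60.0
    oh = np.asarray(oh_flags, dtype=bool)
    both_oh = oh[:-1] & oh[1:]
    return float(np.sum(dt_min[both_oh & (dt_min <= max_gap_min)]))


def entropy(stops: Sequence[StopSegment]) -> float | None:
    """Entropy (nats) of the day's dwell-time distribution over stop clusters.

    p_i is the share of total stop dwell time spent in location cluster i
    (home included); entropy = -sum p_i ln p_i. Requires cluster ids.
    """
    dwell: dict[int, float] = {}
    for s in stops:
        if s.cluster_id is None:
            raise ValueError("stops must carry cluster ids (run cluster_stops first)")
        dwell[s.cluster_id] = dwell.get(s.cluster_id, 0.0) + s.duration_min
    total = sum(dwell.values())
    if total <= 0.0:
        return None
    p = np.array([v / total for v in dwell.values() if v > 0.0])
    return float(-np.sum(p * np.log(p)))


def num_loc(stops: Sequence[StopSegment]) -> int:
    """Number of out-of-home stops that day (repeat visits count each time)."""
    return sum(1 for s in stops if s.is_out_of_home)


def num_uniq_loc(stops: Sequence[StopSegment]) -> int:
    """Distinct out-of-home location clusters across the selected days."""
    return len({s.cluster_id for s in stops if s.is_out_of_home})


# ---------------------------------------------------------------------------
# cross-day overlap and direction


def revisited_ls(
    hulls: Mapping[date, HullResult]
) -> tuple[dict[date, float | None], dict[date, float | None]]:
    """Day-to-day life-space overlap fractions.

    For each day d: RevisitedLS_d = the fraction of d's convex hull covered
    by the union of the other days' hulls; AvgRevisitedLS_d = the mean
    pairwise overlap fraction with each other day. Days with degenerate
    hulls are missing.
    """
    days = sorted(hulls)
    rev: dict[date, float | None] = {}
    avg: dict[date, float | None] = {}
    for d in days:
        h = hulls[d]
        if h.polygon is None or h.area_km2 <= 0.0:
            rev[d] = avg[d] = None
            continue
        others = [hulls[e].polygon for e in days if e != d and hulls[e].polygon is not None]
        if not others:
            rev[d] = avg[d] = None
            continue
        rev[d] = float(h.polygon.intersection(unary_union(others)).area / h.area_km2)
        avg[d] = float(
            np.mean([h.polygon.intersection(o).area / h.area_km2 for o in others])
        )
    return rev, avg


def bearing_max_dist(fixes: Sequence[GpsFix], home: HomeLocation) -> float | None:
    """Initial bearing (radians, 0 = north) from home to the farthest fix."""
    if not fixes:
        return None
    lats = np.array([f.lat for f in fixes])
    lons = np.array([f.lon for f in fixes])
    d = np.atleast_1d(haversine_km(home.lat, home.lon, lats, lons))
    k = int(np.argmax(d))  # earliest fix attains the tie
    if d[k] <= 0.0:
        return None
    return float(bearing_rad(home.lat, home.lon, lats[k], lons[k]))


def circular_sd(bearings: Sequence[float]) -> float | None:
    """Circular standard deviation sqrt(-2 ln Rbar) of a set of bearings.

    Rbar is the mean resultant length of the unit bearing vectors; Rbar = 0
    (e.g. antipodal pair) leaves the SD undefined.
    """
    b = np.asarray([x for x in bearings if x is not None and not np.isnan(x)], dtype=float)
    if b.size < 2:
        return None
    rbar = float(np.hypot(np.mean(np.cos(b)), np.mean(np.sin(b))))
    if rbar <= 1e-12:
        return None
    return math.sqrt(-2.0 * math.log(min(rbar, 1.0)))


# ---------------------------------------------------------------------------
# timing


def _minutes_since_3am(ts) -> float:
    return ((ts.hour * 60 + ts.minute + ts.second / 60.0) - 180.0) % 1440.0


def timing_indicators(
    segday: SegmentedDay, home: HomeLocation
) -> dict[str, float | None]:
    """TimeMaxDist, TimeFirstMove (min since 3 AM) and TimePeriodActive code.

    TimePeriodActive counts out-of-home activities (moves and OH stops) by
    start-time period — morning 06:00-12:00, afternoon 12:00-18:00, evening
    18:00-23:00 — and codes the day 1 (morning > evening activities),
    3 (evening > morning) or 2 (neutral). Activities starting outside
    06:00-23:00 are not counted.
    """
    fixes = segday.day.fixes
    out: dict[str, float | None] = {
        "TimeMaxDist": None,
        "TimeFirstMove": None,
        "TimePeriodActive": None,
    }
    if fixes:
        lats = np.array([f.lat for f in fixes])
        lons = np.array([f.lon for f in fixes])
        d = np.atleast_1d(haversine_km(home.lat, home.lon, lats, lons))
        out["TimeMaxDist"] = _minutes_since_3am(fixes[int(np.argmax(d))].timestamp)
    if segday.moves:
        out["TimeFirstMove"] = _minutes_since_3am(min(m.start for m in segday.moves))
    starts = [m.start for m in segday.moves] + [
        s.arrival for s in segday.stops if s.is_out_of_home
    ]
    morning = sum(1 for t in starts if 6 <= t.hour < 12)
    evening = sum(1 for t in starts if 18 <= t.hour < 23)
    out["TimePeriodActive"] = 1.0 if morning > evening else (3.0 if evening > morning else 2.0)
    return out


# ---------------------------------------------------------------------------
# orchestration


def compute_daily_indicators(
    segday: SegmentedDay, home: HomeLocation, toh_gap_min: float = 60.0
) -> dict[str, float | None]:
    """All per-day indicator values for one annotated, clustered day.

    Cross-day indicators (NumUniqLoc, RevisitedLS, AvgRevisitedLS and the
    weekly circular SD of SDDirMaxDist) are computed at week level; here
    SDDirMaxDist is the day's bearing and the overlap entries are left out.
    Requires ``annotate_oh`` and ``cluster_stops`` to have run.
    """
    fixes = segday.day.fixes
    xy = project_local(fixes, home)
    hull = convex_hull(xy)
    ell = sde(xy)
    vals: dict[str, float | None] = {
        "MaxDist": max_dist(fixes, home),
        "CHull": hull.area_km2,
        "SDE": ell.area_km2 if ell is not None else None,
        "LocVar": loc_var(xy),
        "TOH": toh(fixes, segday.fix_oh, toh_gap_min) if segday.fix_oh is not None else None,
        "Entropy": entropy(segday.stops) if segday.stops else None,
        "NumLoc": float(num_loc(segday.stops)),
        "GravCompact": grav_compact(hull),
        "Maj2MinAxis": maj2min(ell),
        "SDDirMaxDist": bearing_max_dist(fixes, home),
    }
    vals.update(trip_indicators(segday.moves))
    vals.update(timing_indicators(segday, home))
    return vals


def aggregate_week(
    daily: Mapping[date, Mapping[str, float | None]],
    r_days: Sequence[date],
    m_days: Sequence[date],
    week_level: Mapping[str, float | None] | None = None,
) -> dict[str, float]:
    """Aggregate daily values to the weekly indicator vector.

    Median over the indicator's scheme days (R or M), except SDDirMaxDist
    (circular SD of the M-day bearings) and TimePeriodActive (mean).
    ``week_level`` supplies indicators computed directly at week level
    (NumUniqLoc, RevisitedLS, AvgRevisitedLS). Missing daily values are
    dropped; an indicator with no value at all is NaN.
    """
    week_level = dict(week_level or {})
    out: dict[str, float] = {}
    for name in INDICATOR_NAMES:
        if name in week_level:
            v = week_level[name]
            out[name] = float(v) if v is not None else float("nan")
            continue
        days = m_days if DAY_SELECTION_SCHEME[name] == "M" else r_days
        values = [daily[d].get(name) for d in days if d in daily]
        values = [v for v in values if v is not None and not np.isnan(v)]
        if not values:
            out[name] = float("nan")
        elif name == "SDDirMaxDist":
            csd = circular_sd(values)
            out[name] = float(csd) if csd is not None else float("nan")
        elif name == "TimePeriodActive":
            out[name] = float(np.mean(values))
        else:
            out[name] = float(np.median(values))
    return out
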