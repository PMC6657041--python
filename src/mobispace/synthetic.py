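"""Synthetic GPS cohorts and indicator matrices with known ground truth.

Emulates roughly one week of smartphone GPS from community-dwelling older
adults: a home anchor, out-of-home stop visits drawn from a persistent
destination pool (day-to-day routine), walking (3-6 km/h) and motorised
(30-90 km/h) trips along straight paths, isotropic GPS noise, and
in-building signal gaps at stops. Every planted stop, trip and scheduled
out-of-home minute is returned as ground truth, so segmentation and the
indicator suite can be validated end to end.

A separate factor-model simulator plants a known orthogonal loading
structure on the 20 weekly indicators for validating the factor-analysis
stage independently of the GPS pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectory import GpsFix, HomeLocation, Trajectory, unproject_local

__all__ = [
    "MobilityProfile",
    "PlantedStop",
    "PlantedTrip",
    "DayTruth",
    "GroundTruth",
    "PlantedFactorSpec",
    "DEFAULT_LOADING_PATTERN",
    "generate_week",
    "generate_cohort",
    "generate_indicator_matrix",
]

#: Fixed-offset local zone (central Europe, summer); a fixed offset keeps
#: logical-day arithmetic free of DST corner cases.
TZ = timezone(timedelta(hours=2))

#: Study week starts on a Monday 3 AM so days 6-7 are the weekend.
WEEK_START = datetime(2023, 5, 1, 3, 0, tzinfo=TZ)

HOME_BUFFER_KM = 0.15  # mirrors the pipeline's out-of-home buffer
DAY_S = 86400.0

WALK_SPEED_KMH = (3.0, 6.0)
VEHICLE_SPEED_KMH = (30.0, 90.0)
MIN_TRIP_MIN = 4.0  # every planted trip must qualify as a move (> 3 min)
VEHICLE_MIN_DIST_KM = 2.0  # below this a trip is always walked

_TIMING_WINDOWS = {"morning": (7.0, 12.0), "neutral": (8.5, 18.0), "evening": (13.0, 20.0)}


@dataclass(frozen=True)
class MobilityProfile:
    """Parameters of one participant's simulated mobility.

    ``extent_scale_km`` is the typical out-of-home destination distance;
    ``n_oh_per_day`` the Poisson rate of daily out-of-home visits;
    ``atm_share`` the propensity to walk a trip (trips under 2 km are
    always walked, trips over 5 km always motorised); ``routine_overlap``
    the probability a visit reuses a previous destination; ``elongation``
    the axis ratio of the destination cloud around home; ``timing_mode``
    shifts visit start times toward morning or evening; ``gap_rate_per_h``
    the rate of in-building signal loss episodes while at a stop.
    """

    home: HomeLocation
    extent_scale_km: float = 2.0
    n_oh_per_day: float = 2.0
    atm_share: float = 0.6
    routine_overlap: float = 0.5
    elongation: float = 1.5
    timing_mode: str = "neutral"  # morning | neutral | evening
    sampling_interval_s: float = 60.0
    noise_sd_m: float = 25.0
    gap_rate_per_h: float = 0.1

    def __post_init__(self):
        if self.timing_mode not in _TIMING_WINDOWS:
            raise ValueError(f"unknown timing_mode: {self.timing_mode}")
        for name in (
            "extent_scale_km",
            "n_oh_per_day",
            "sampling_interval_s",
            "noise_sd_m",
            "gap_rate_per_h",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("atm_share", "routine_overlap"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class PlantedStop:
    lat: float
    lon: float
    arrival: datetime  # crossing into the 150 m stop region
    departure: datetime  # crossing out of the 150 m stop region
    is_oh: bool


@dataclass(frozen=True)
class PlantedTrip:
    mode: str  # "walk" or "vehicle"
    start: datetime
    end: datetime
    length_km: float
    speed_kmh: float


@dataclass
class DayTruth:
    logical_date: date
    stops: list[PlantedStop]
    trips: list[PlantedTrip]
    scheduled_oh_min: float


@dataclass
class GroundTruth:
    participant_id: str
    days: list[DayTruth]

    @property
    def total_scheduled_oh_min(self) -> float:
        return sum(d.scheduled_oh_min for d in self.days)


@dataclass
class _Event:
    t0: float  # seconds since week start
    t1: float
    a: np.ndarray  # planar km relative to home
    b: np.ndarray
    kind: str  # home | visit | trip
    speed_kmh: float = 0.0


# ---------------------------------------------------------------------------
# trajectory simulation


def _draw_destination(
    pool: list[np.ndarray],
    profile: MobilityProfile,
    rng: np.random.Generator,
    axis_angle: float,
) -> np.ndarray:
    if pool and rng.random() < profile.routine_overlap:
        return pool[int(rng.integers(len(pool)))]
    s_major = max(profile.extent_scale_km, 0.6)
    s_minor = s_major / max(profile.elongation, 1.0)
    u = rng.standard_normal(2) * (s_major, s_minor)
    c, s = math.cos(axis_angle), math.sin(axis_angle)
    xy = np.array([c * u[0] - s * u[1], s * u[0] + c * u[1]])
    r = float(np.hypot(*xy))
    if r < 0.5:  # keep destinations clearly outside the home buffer
        xy = xy * (0.5 / max(r, 1e-9))
    pool.append(xy)
    return xy


def _schedule_week(profile: MobilityProfile, n_days: int, rng: np.random.Generator):
    """Build the week's event timeline, trips and scheduled OH minutes."""
    axis_angle = float(rng.uniform(0.0, math.pi))
    pool: list[np.ndarray] = []
    home_xy = np.zeros(2)
    events: list[_Event] = []
    trips_by_day: dict[int, list[tuple[str, float, float, float, float]]] = {
        d: [] for d in range(n_days)
    }
    oh_minutes = np.zeros(n_days)

    cursor = 0.0
    for d in range(n_days):
        day0 = d * DAY_S
        lo, hi = _TIMING_WINDOWS[profile.timing_mode]
        n_visits = int(rng.poisson(profile.n_oh_per_day))
        starts = np.sort(rng.uniform((lo - 3.0) * 3600.0, (hi - 3.0) * 3600.0, size=n_visits))
        for st in starts:
            t_depart = max(day0 + st, cursor + 15.0 * 60.0)  # >= 15 min home dwell
            dest = _draw_destination(pool, profile, rng, axis_angle)
            dist = float(np.hypot(*dest))
            walk = dist < VEHICLE_MIN_DIST_KM or (
                dist <= 5.0 and rng.random() < profile.atm_share
            )
            if walk:
                speed = float(rng.uniform(*WALK_SPEED_KMH))
                mode = "walk"
            else:
                # cap the speed so even a short hop stays above the 3-min
                # move threshold; floor keeps the p90 clearly motorised
                speed = min(float(rng.uniform(*VEHICLE_SPEED_KMH)), dist * 60.0 / MIN_TRIP_MIN)
                speed = max(speed, 30.0)
                mode = "vehicle"
            trip_s = dist / speed * 3600.0
            dwell_s = float(rng.uniform(30.0, 120.0)) * 60.0
            t_arr = t_depart + trip_s
            t_leave = t_arr + dwell_s
            t_home = t_leave + trip_s
            if t_home > day0 + DAY_S - 3600.0:  # home at least 1 h before 3 AM
                continue
            events.append(_Event(cursor, t_depart, home_xy, home_xy, "home"))
            events.append(_Event(t_depart, t_arr, home_xy, dest, "trip", speed))
            events.append(_Event(t_arr, t_leave, dest, dest, "visit"))
            events.append(_Event(t_leave, t_home, dest, home_xy, "trip", speed))
            trips_by_day[d].append((mode, t_depart, t_arr, dist, speed))
            trips_by_day[d].append((mode, t_leave, t_home, dist, speed))
            boundary_s = HOME_BUFFER_KM / speed * 3600.0
            oh_minutes[d] += (t_home - t_depart - 2.0 * boundary_s) / 60.0
            cursor = t_home
    events.append(_Event(cursor, n_days * DAY_S, home_xy, home_xy, "home"))
    return events, trips_by_day, oh_minutes


def _sample_fixes(
    events: list[_Event],
    profile: MobilityProfile,
    rng: np.random.Generator,
    week_start: datetime,
    participant_id: str,
    n_days: int,
) -> list[GpsFix]:
    t_grid = np.arange(0.0, n_days * DAY_S, profile.sampling_interval_s)
    xy = np.zeros((len(t_grid), 2))
    starts = np.array([e.t0 for e in events])
    idx = np.clip(np.searchsorted(starts, t_grid, side="right") - 1, 0, len(events) - 1)
    for k, e in enumerate(events):
        m = idx == k
        if not m.any():
            continue
        if e.kind == "trip":
            frac = np.clip((t_grid[m] - e.t0) / max(e.t1 - e.t0, 1e-9), 0.0, 1.0)
            xy[m] = e.a + frac[:, None] * (e.b - e.a)
        else:
            xy[m] = e.a

    # in-building signal gaps: contiguous fix drop-outs at stops, kept
    # under 60 min so the out-of-home time rule can interpolate across them
    drop = np.zeros(len(t_grid), dtype=bool)
    for e in events:
        if e.kind == "trip":
            continue
        hours = (e.t1 - e.t0) / 3600.0
        for _ in range(int(rng.poisson(profile.gap_rate_per_h * hours))):
            g0 = rng.uniform(e.t0, e.t1)
            g1 = min(g0 + rng.uniform(10.0, 40.0) * 60.0, e.t1)
            drop |= (t_grid >= g0) & (t_grid < g1)

    xy = xy + rng.standard_normal(xy.shape) * (profile.noise_sd_m / 1000.0)
    keep = ~drop
    latlon = unproject_local(xy[keep], profile.home)
    times = t_grid[keep]
    return [
        GpsFix(
            participant_id,
            week_start + timedelta(seconds=float(t)),
            float(la),
            float(lo),
        )
        for t, (la, lo) in zip(times, latlon)
    ]


def _ground_truth(
    events: list[_Event],
    trips_by_day: dict[int, list[tuple[str, float, float, float, float]]],
    oh_minutes: np.ndarray,
    profile: MobilityProfile,
    week_start: datetime,
    n_days: int,
    participant_id: str,
) -> GroundTruth:
    ts = lambda s: week_start + timedelta(seconds=float(s))

    # stop-region boundary crossings: extend anchored events into the
    # adjoining trips by the time needed to cover the 150 m region radius
    stop_windows: list[tuple[float, float, np.ndarray]] = []
    for k, e in enumerate(events):
        if e.kind == "trip":
            continue
        arr, dep = e.t0, e.t1
        if k > 0 and events[k - 1].kind == "trip":
            arr -= HOME_BUFFER_KM / events[k - 1].speed_kmh * 3600.0
        if k + 1 < len(events) and events[k + 1].kind == "trip":
            dep += HOME_BUFFER_KM / events[k + 1].speed_kmh * 3600.0
        stop_windows.append((arr, dep, e.a))

    days = []
    for d in range(n_days):
        w0, w1 = d * DAY_S, (d + 1) * DAY_S
        stops = []
        for arr, dep, xy in stop_windows:
            a, b = max(arr, w0), min(dep, w1)
            if b <= a:
                continue
            lat, lon = unproject_local(xy, profile.home)[0]
            is_oh = float(np.hypot(*xy)) > HOME_BUFFER_KM
            stops.append(PlantedStop(float(lat), float(lon), ts(a), ts(b), is_oh))
        trips = [
            PlantedTrip(mode, ts(t0), ts(t1), dist, speed)
            for mode, t0, t1, dist, speed in trips_by_day[d]
        ]
        days.append(
            DayTruth(
                logical_date=(week_start + timedelta(seconds=w0)).date(),
                stops=stops,
                trips=trips,
                scheduled_oh_min=float(oh_minutes[d]),
            )
        )
    return GroundTruth(participant_id, days)


def generate_week(
    profile: MobilityProfile,
    n_days: int = 7,
    rng_seed: int = 0,
    participant_id: str = "P000",
    week_start: datetime = WEEK_START,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one participant-week; deterministic given the seed.

    Each day: night at home, a Poisson number of out-of-home visits at
    destinations from a persistent pool, connected by walk or vehicle trips
    along straight paths, fixes every ``sampling_interval_s`` with
    isotropic Gaussian noise, and fix drop-outs at stops emulating
    in-building signal loss. Planted stop arrival/departure times are the
    crossings of the 150 m stop region — the construct the segmentation
    stage estimates.
    """
    rng = np.random.default_rng(rng_seed)
    events, trips_by_day, oh_minutes = _schedule_week(profile, n_days, rng)
    fixes = _sample_fixes(events, profile, rng, week_start, participant_id, n_days)
    truth = _ground_truth(
        events, trips_by_day, oh_minutes, profile, week_start, n_days, participant_id
    )
    return Trajectory(participant_id, fixes), truth


def planted_schedule_day(
    rng_seed: int = 0,
    n_visits: int = 3,
    sampling_s: float = 30.0,
    noise_m: float = 25.0,
    home: HomeLocation | None = None,
    participant_id: str = "V000",
) -> tuple[Trajectory, GroundTruth]:
    """One validation day with a tightly controlled stop/move schedule.

    Destinations 1.5-5 km from home with pairwise separation >= 500 m,
    motorised transitions (40-60 km/h, so stop-region boundary crossings
    are sharp relative to the sampling interval), dwells 15-90 min, no
    signal gaps. Used to measure how precisely the segmentation stage
    recovers planted stop boundaries.
    """
    rng = np.random.default_rng(rng_seed)
    home = home or HomeLocation(*COHORT_CENTER)
    profile = MobilityProfile(
        home=home,
        sampling_interval_s=sampling_s,
        noise_sd_m=noise_m,
        gap_rate_per_h=0.0,
    )
    home_xy = np.zeros(2)
    dests: list[np.ndarray] = []
    while len(dests) < n_visits:
        r = rng.uniform(1.5, 5.0)
        th = rng.uniform(0.0, 2.0 * math.pi)
        xy = np.array([r * math.sin(th), r * math.cos(th)])
        if all(float(np.hypot(*(xy - d))) >= 0.5 for d in dests):
            dests.append(xy)

    events: list[_Event] = []
    trips: list[tuple[str, float, float, float, float]] = []
    oh_min = 0.0
    cursor = 0.0
    day_hours = rng.uniform(6.0, 14.0) / n_visits  # spread visits over the day
    for dest in dests:
        t_depart = cursor + rng.uniform(15.0, 60.0 * day_hours) * 60.0
        dist = float(np.hypot(*dest))
        speed = float(rng.uniform(40.0, 60.0))
        trip_s = dist / speed * 3600.0
        dwell_s = rng.uniform(15.0, 90.0) * 60.0
        t_arr, t_leave = t_depart + trip_s, t_depart + trip_s + dwell_s
        t_home = t_leave + trip_s
        if t_home > DAY_S - 3600.0:
            break
        events.append(_Event(cursor, t_depart, home_xy, home_xy, "home"))
        events.append(_Event(t_depart, t_arr, home_xy, dest, "trip", speed))
        events.append(_Event(t_arr, t_leave, dest, dest, "visit"))
        events.append(_Event(t_leave, t_home, dest, home_xy, "trip", speed))
        trips.append(("vehicle", t_depart, t_arr, dist, speed))
        trips.append(("vehicle", t_leave, t_home, dist, speed))
        oh_min += (t_home - t_depart - 2.0 * HOME_BUFFER_KM / speed * 3600.0) / 60.0
        cursor = t_home
    events.append(_Event(cursor, DAY_S, home_xy, home_xy, "home"))

    fixes = _sample_fixes(events, profile, rng, WEEK_START, participant_id, 1)
    truth = _ground_truth(events, {0: trips}, np.array([oh_min]), profile, WEEK_START, 1, participant_id)
    return Trajectory(participant_id, fixes), truth


# ---------------------------------------------------------------------------
# cohort simulation

COHORT_CENTER = (50.94, 6.96)  # an urban region in western Germany


def _draw_profile(rng: np.random.Generator, home: HomeLocation) -> MobilityProfile:
    return MobilityProfile(
        home=home,
        extent_scale_km=float(np.clip(rng.lognormal(math.log(2.5), 0.7), 0.8, 12.0)),
        n_oh_per_day=float(rng.uniform(1.0, 3.5)),
        atm_share=float(rng.beta(2.5, 2.0)),
        routine_overlap=float(rng.uniform(0.3, 0.8)),
        elongation=float(rng.uniform(1.0, 3.0)),
        timing_mode=str(rng.choice(["morning", "neutral", "evening"], p=[0.35, 0.4, 0.25])),
        sampling_interval_s=60.0,
        noise_sd_m=float(rng.uniform(10.0, 40.0)),
        gap_rate_per_h=float(rng.uniform(0.05, 0.25)),
    )


def generate_cohort(
    n: int = 95,
    rng_seed: int = 0,
    n_days: int = 7,
    exclusion_fraction: float = 0.05,
) -> list[tuple[Trajectory, GroundTruth, HomeLocation, MobilityProfile]]:
    """Simulate a cohort of participant-weeks with per-participant profiles.

    Returns (trajectory, ground truth, address-based home, profile) per
    participant. The address home sits within 50 m of the true home for
    most participants; a configurable fraction gets an address more than
    170 m away to exercise the home-match exclusion rule.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    out = []
    for i in range(n):
        # homes scattered over an 8 km urban disk
        r = 8.0 * math.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * math.pi)
        lat, lon = unproject_local(
            np.array([r * math.sin(th), r * math.cos(th)]), COHORT_CENTER
        )[0]
        home = HomeLocation(float(lat), float(lon), source="gps")
        profile = _draw_profile(rng, home)
        pid = f"P{i:03d}"
        traj, truth = generate_week(
            profile, n_days=n_days, rng_seed=int(rng.integers(2**31)), participant_id=pid
        )
        # address-based home: small survey error, occasionally a mismatch
        err_m = rng.uniform(200.0, 400.0) if rng.random() < exclusion_fraction else rng.uniform(0.0, 50.0)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        alat, alon = unproject_local(
            np.array([err_m / 1000.0 * math.sin(phi), err_m / 1000.0 * math.cos(phi)]),
            home,
        )[0]
        address = HomeLocation(float(alat), float(alon), source="address")
        out.append((traj, truth, address, profile))
    return out


# ---------------------------------------------------------------------------
# planted factor structure

#: Default planted structure: six latent mobility dimensions — life-space
#: extent, quantity of out-of-home activity, active-transport time,
#: life-space stability, life-space elongation, timing of mobility — with
#: loading magnitudes in [0.6, 0.9].
DEFAULT_LOADING_PATTERN: dict[str, tuple[int, float]] = {
    "MaxDist": (0, 0.87),
    "CHull": (0, 0.90),
    "SDE": (0, 0.90),
    "LengthPerTrip": (0, 0.70),
    "LocVar": (0, 0.79),
    "DurPTM": (0, 0.60),
    "TOH": (1, 0.64),
    "Entropy": (1, 0.76),
    "NumLoc": (1, 0.83),
    "NumUniqLoc": (1, 0.60),
    "DurATM": (2, 0.90),
    "MaxDurATM": (2, 0.90),
    "RevisitedLS": (3, 0.90),
    "AvgRevisitedLS": (3, 0.74),
    "SDDirMaxDist": (3, -0.60),
    "GravCompact": (4, 0.90),
    "Maj2MinAxis": (4, 0.72),
    "TimeMaxDist": (5, 0.74),
    "TimeFirstMove": (5, 0.65),
    "TimePeriodActive": (5, 0.60),
}


@dataclass(frozen=True)
class PlantedFactorSpec:
    """A known orthogonal factor structure over the 20 indicators."""

    n_factors: int = 6
    loading_pattern: dict[str, tuple[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_LOADING_PATTERN)
    )
    n_rows: int = 95

    def loading_matrix(self) -> pd.DataFrame:
        lam = pd.DataFrame(
            0.0,
            index=list(self.loading_pattern),
            columns=[f"F{i + 1}" for i in range(self.n_factors)],
        )
        for name, (f, lo) in self.loading_pattern.items():
            if not 0 <= f < self.n_factors:
                raise ValueError(f"factor index out of range for {name}")
            if not 0.0 < abs(lo) < 1.0:
                raise ValueError(f"loading magnitude must be in (0, 1) for {name}")
            lam.loc[name, f"F{f + 1}"] = lo
        return lam


def generate_indicator_matrix(
    spec: PlantedFactorSpec | None = None, rng_seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an indicator matrix from x = Lambda f + eps with known loadings.

    Orthonormal standard-normal factors, diagonal uniquenesses
    1 - loading^2 (unit-variance columns). Returns (data, true loadings).
    """
    spec = spec or PlantedFactorSpec()
    lam = spec.loading_matrix()
    lam_np = lam.to_numpy()
    psi = 1.0 - np.sum(lam_np**2, axis=1)
    if np.any(psi <= 0.0):
        raise ValueError("implied covariance not positive definite")
    rng = np.random.default_rng(rng_seed)
    f = rng.standard_normal((spec.n_rows, spec.n_factors))
    eps = rng.standard_normal((spec.n_rows, len(lam))) * np.sqrt(psi)
    x = f @ lam_np.T + eps
    return pd.DataFrame(x, columns=list(lam.index)), lam
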