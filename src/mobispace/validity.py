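"""Valid-day rules, participant inclusion and randomized study-day selection.

A study day is valid when the GPS registration period (first to last fix,
gaps ignored) reaches the wear-time threshold, at least one stop was found,
and — on the first/last study day — no fix lies within 200 m of the lab
(device pickup/return visits). Participants are included when their
GPS-detected home matches the address-based home within 170 m, enough valid
days of the right weekend/weekday composition exist, and at least three
valid days (one weekend, two weekdays) contain a move.

Weekly indicators are computed on a random subset of the valid days: the R
scheme draws 1 weekend day plus ``min_days - 1`` weekdays from all valid
days; the M scheme draws 1 weekend day plus 2 weekdays from valid days that
contain at least one move.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np

from .segmentation import SegmentedDay
from .trajectory import HomeLocation, haversine_km

__all__ = [
    "DayValidity",
    "InclusionDecision",
    "DaySelection",
    "assess_day",
    "include_participant",
    "select_days",
]

LAB_RADIUS_M = 200.0
HOME_MATCH_M = 170.0


@dataclass
class DayValidity:
    logical_date: date
    wear_hours: float
    has_stop: bool
    lab_visit: bool
    valid: bool
    has_move: bool
    weekend: bool


@dataclass
class InclusionDecision:
    participant_id: str
    included: bool
    reasons: list[str]
    valid_days: list[DayValidity]


@dataclass
class DaySelection:
    """Selected study days: R (fully random) and M (move-required) sets."""

    r_days: list[date]
    m_days: list[date]
    seed: int


def assess_day(
    segday: SegmentedDay,
    min_hours: float = 8.0,
    lab: tuple[float, float] | None = None,
    is_edge_day: bool = False,
    lab_radius_m: float = LAB_RADIUS_M,
) -> DayValidity:
    """Assess one segmented day against the valid-day rules.

    Wear time is the span between the first and last fix of the day,
    independent of gaps; the lab rule applies only on edge (first/last)
    study days.
    """
    fixes = segday.day.fixes
    wear_h = (
        (fixes[-1].timestamp - fixes[0].timestamp).total_seconds() / 3600.0 if fixes else 0.0
    )
    lab_visit = False
    if is_edge_day and lab is not None and fixes:
        lats = np.array([f.lat for f in fixes])
        lons = np.array([f.lon for f in fixes])
        lab_visit = bool(
            np.any(np.atleast_1d(haversine_km(lab[0], lab[1], lats, lons)) * 1000.0 <= lab_radius_m)
        )
    has_stop = len(segday.stops) > 0
    return DayValidity(
        logical_date=segday.day.logical_date,
        wear_hours=wear_h,
        has_stop=has_stop,
        lab_visit=lab_visit,
        valid=(wear_h >= min_hours) and has_stop and not lab_visit,
        has_move=len(segday.moves) > 0,
        weekend=segday.day.weekend,
    )


def include_participant(
    participant_id: str,
    days: list[DayValidity],
    home: HomeLocation,
    address: HomeLocation | None = None,
    min_days: int = 3,
    nonhabitual: bool = False,
    home_match_m: float = HOME_MATCH_M,
) -> InclusionDecision:
    """Apply the participant-level inclusion rules.

    Requirements: GPS/address home agreement below 170 m (when an address
    exists); at least ``min_days`` valid days composed of >= 1 weekend day
    and >= min_days - 1 weekdays; at least one valid weekend day and two
    valid weekdays each containing a move; no self-reported non-habitual
    movement.
    """
    reasons: list[str] = []
    if address is not None:
        if haversine_km(home.lat, home.lon, address.lat, address.lon) * 1000.0 >= home_match_m:
            reasons.append("home_mismatch")
    valid = [d for d in days if d.valid]
    we = [d for d in valid if d.weekend]
    wd = [d for d in valid if not d.weekend]
    if len(valid) < min_days or not we or len(wd) < min_days - 1:
        if not we:
            reasons.append("no_weekend")
        else:
            reasons.append("too_few_valid_days")
    if not any(d.has_move for d in we) or sum(d.has_move for d in wd) < 2:
        reasons.append("too_few_move_days")
    if nonhabitual:
        reasons.append("nonhabitual_movement")
    return InclusionDecision(
        participant_id=participant_id,
        included=not reasons,
        reasons=reasons,
        valid_days=valid,
    )


def select_days(days: list[DayValidity], min_days: int = 3, rng_seed: int = 0) -> DaySelection:
    """Draw the R and M study-day subsets, reproducibly under ``rng_seed``.

    R: one valid weekend day + ``min_days - 1`` valid weekdays, uniformly.
    M: one weekend day + two weekdays among valid days with >= 1 move.
    """
    rng = np.random.default_rng(rng_seed)
    valid = [d for d in days if d.valid]
    we = sorted(d.logical_date for d in valid if d.weekend)
    wd = sorted(d.logical_date for d in valid if not d.weekend)
    if not we or len(wd) < min_days - 1:
        raise ValueError("not enough qualifying days for R selection")
    r_days = [we[rng.integers(len(we))]] + [
        wd[i] for i in sorted(rng.choice(len(wd), size=min_days - 1, replace=False))
    ]
    m_we = sorted(d.logical_date for d in valid if d.weekend and d.has_move)
    m_wd = sorted(d.logical_date for d in valid if not d.weekend and d.has_move)
    if not m_we or len(m_wd) < 2:
        raise ValueError("not enough qualifying days for M selection")
    m_days = [m_we[rng.integers(len(m_we))]] + [
        m_wd[i] for i in sorted(rng.choice(len(m_wd), size=2, replace=False))
    ]
    return DaySelection(r_days=r_days, m_days=m_days, seed=rng_seed)
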