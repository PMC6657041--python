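"""End-to-end orchestration: fixes -> segments -> validity -> indicators -> EFA.

One :class:`PipelineConfig` carries every threshold of the processing and
inclusion rules with its default. :func:`process_cohort` turns raw
trajectories into the participants x 20 weekly indicator matrix for a given
(min valid days, min wear hours) data condition and day-selection seed;
:func:`run_cohort_study` repeats the EFA over conditions and re-drawn study
days. The numbered scripts under ``analysis/`` are thin drivers over these
functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import efa as efa_mod
from .indicators import (
    DAY_SELECTION_SCHEME,
    INDICATOR_NAMES,
    INDICATOR_TAXONOMY,
    aggregate_week,
    compute_daily_indicators,
    convex_hull,
    num_uniq_loc,
    revisited_ls,
)
from .segmentation import SegmentedDay, annotate_oh, cluster_stops, detect_home, segment_day
from .trajectory import (
    DayTrajectory,
    HomeLocation,
    Trajectory,
    project_local,
    remove_outliers,
    split_days,
)
from .validity import DaySelection, assess_day, include_participant, select_days

__all__ = [
    "PipelineConfig",
    "ParticipantWeek",
    "preprocess_participant",
    "participant_week_indicators",
    "process_cohort",
    "run_cohort_study",
    "write_segments_csv",
    "descriptive_stats",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every processing threshold, with its default value."""

    max_speed_kmh: float = 330.0  # outlier filter (fastest German train)
    day_boundary: time = time(3, 0)
    stop_roam_m: float = 150.0
    min_stop_min: float = 5.0
    intra_stop_gap_min: float = 60.0
    min_move_min: float = 3.0
    merge_dist_m: float = 150.0
    merge_dt_min: float = 60.0
    mode_threshold_kmh: float = 25.0
    home_buffer_m: float = 150.0
    stop_cluster_eps_m: float = 60.0
    stop_cluster_min_pts: int = 2
    home_eps_m: float = 60.0
    home_min_pts: int = 3
    address_match_m: float = 170.0
    lab_radius_m: float = 200.0
    toh_gap_min: float = 60.0
    #: Table-4 style grid of (min valid days, min wear hours) conditions.
    conditions: tuple[tuple[int, float], ...] = (
        (3, 8.0),
        (4, 8.0),
        (4, 9.0),
        (4, 10.0),
        (5, 10.0),
    )
    n_runs: int = 10

    def to_json(self) -> str:
        d = {k: (v.isoformat() if isinstance(v, time) else v) for k, v in self.__dict__.items()}
        return json.dumps(d, indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["day_boundary"] = time.fromisoformat(d["day_boundary"])
        d["conditions"] = tuple(tuple(c) for c in d["conditions"])
        return cls(**d)


@dataclass
class ParticipantWeek:
    """One participant's preprocessed week: segmented days plus metadata."""

    participant_id: str
    segdays: dict[date, SegmentedDay]
    address: HomeLocation | None
    nonhabitual: bool = False


def preprocess_participant(
    traj: Trajectory,
    address: HomeLocation | None = None,
    config: PipelineConfig = PipelineConfig(),
    nonhabitual: bool = False,
) -> ParticipantWeek:
    """Outlier removal, day splitting and segmentation for one participant."""
    traj = remove_outliers(traj, config.max_speed_kmh)
    days = split_days(traj, config.day_boundary)
    segdays = {
        d.logical_date: segment_day(
            d,
            home=None,
            roam_m=config.stop_roam_m,
            min_stop_min=config.min_stop_min,
            intra_gap_min=config.intra_stop_gap_min,
            min_move_min=config.min_move_min,
            merge_dist_m=config.merge_dist_m,
            merge_dt_min=config.merge_dt_min,
        )
        for d in days
    }
    return ParticipantWeek(traj.participant_id, segdays, address, nonhabitual)


def _condition_validity(
    pweek: ParticipantWeek,
    min_hours: float,
    lab: tuple[float, float] | None,
    config: PipelineConfig,
):
    dates = sorted(pweek.segdays)
    edge = {dates[0], dates[-1]} if dates else set()
    return [
        assess_day(
            pweek.segdays[d],
            min_hours=min_hours,
            lab=lab,
            is_edge_day=d in edge,
            lab_radius_m=config.lab_radius_m,
        )
        for d in dates
    ]


def participant_week_indicators(
    pweek: ParticipantWeek,
    home: HomeLocation,
    selection: DaySelection,
    config: PipelineConfig = PipelineConfig(),
) -> dict[str, float]:
    """The 20 weekly indicator values for one participant and day selection.

    Out-of-home annotation uses the supplied home; stop clusters are
    assigned jointly over the union of the selected days, then daily values
    are computed per scheme day and aggregated (median / circular SD /
    mean). Day-to-day hull overlap and the unique-location count are
    computed across the M days.
    """
    sel_dates = sorted(set(selection.r_days) | set(selection.m_days))
    segdays = {d: pweek.segdays[d] for d in sel_dates}
    for sd in segdays.values():
        annotate_oh(sd, home, config.home_buffer_m)
    all_stops = [s for d in sel_dates for s in segdays[d].stops]
    cluster_stops(all_stops, config.stop_cluster_eps_m, config.stop_cluster_min_pts)

    daily = {
        d: compute_daily_indicators(segdays[d], home, config.toh_gap_min) for d in sel_dates
    }

    m_hulls = {
        d: convex_hull(project_local(segdays[d].day.fixes, home)) for d in selection.m_days
    }
    rev, avg = revisited_ls(m_hulls)
    for d in selection.m_days:
        daily[d]["RevisitedLS"] = rev[d]
        daily[d]["AvgRevisitedLS"] = avg[d]

    m_stops = [s for d in selection.m_days for s in segdays[d].stops]
    week_level = {"NumUniqLoc": float(num_uniq_loc(m_stops))}
    return aggregate_week(daily, selection.r_days, selection.m_days, week_level)


def process_cohort(
    cohort: Sequence[tuple[Trajectory, HomeLocation | None]] | Sequence[ParticipantWeek],
    condition: tuple[int, float] = (3, 8.0),
    run_seed: int = 0,
    lab: tuple[float, float] | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weekly indicator matrix for one data condition and selection seed.

    ``cohort`` is a sequence of (trajectory, address home) pairs or of
    already-preprocessed :class:`ParticipantWeek` objects. Returns
    (indicator matrix indexed by participant, inclusion report).
    """
    min_days, min_hours = condition
    pweeks = [
        p if isinstance(p, ParticipantWeek) else preprocess_participant(p[0], p[1], config)
        for p in cohort
    ]
    rows, report = {}, []
    for k, pw in enumerate(pweeks):
        entry = {"participant_id": pw.participant_id, "included": False, "reasons": ""}
        try:
            days = _condition_validity(pw, min_hours, lab, config)
            valid_dates = {d.logical_date for d in days if d.valid}
            valid_days = [pw.segdays[d].day for d in sorted(valid_dates)]
            home = detect_home(
                valid_days, pw.address, config.home_eps_m, config.home_min_pts
            )
            decision = include_participant(
                pw.participant_id,
                days,
                home,
                pw.address,
                min_days=min_days,
                nonhabitual=pw.nonhabitual,
                home_match_m=config.address_match_m,
            )
            entry["n_valid_days"] = len(valid_dates)
            entry["reasons"] = ";".join(decision.reasons)
            if decision.included:
                selection = select_days(days, min_days, rng_seed=run_seed * 100003 + k)
                rows[pw.participant_id] = participant_week_indicators(
                    pw, home, selection, config
                )
                entry["included"] = True
        except ValueError as exc:
            entry["reasons"] = str(exc)
        report.append(entry)
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(INDICATOR_NAMES))
    matrix.index.name = "participant_id"
    return matrix, pd.DataFrame(report)


def run_cohort_study(
    pweeks: Sequence[ParticipantWeek],
    config: PipelineConfig = PipelineConfig(),
    conditions: Sequence[tuple[int, float]] | None = None,
    n_runs: int | None = None,
    base_seed: int = 0,
    lab: tuple[float, float] | None = None,
) -> dict:
    """Repeated EFA over data conditions, re-drawing study days per run."""

    def matrix_source(condition, run_seed):
        matrix, _ = process_cohort(pweeks, condition, run_seed, lab, config)
        return matrix

    return efa_mod.run_study(
        matrix_source,
        conditions if conditions is not None else config.conditions,
        n_runs if n_runs is not None else config.n_runs,
        base_seed,
    )


# ---------------------------------------------------------------------------
# reports


def write_segments_csv(pweeks: Sequence[ParticipantWeek], out_dir: str | Path) -> None:
    """Write per-stop and per-move CSVs for a preprocessed cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stops, moves = [], []
    for pw in pweeks:
        for d, sd in sorted(pw.segdays.items()):
            for s in sd.stops:
                stops.append(
                    dict(
                        participant_id=pw.participant_id,
                        logical_date=d.isoformat(),
                        center_lat=s.center_lat,
                        center_lon=s.center_lon,
                        arrival=s.arrival.isoformat(),
                        departure=s.departure.isoformat(),
                        is_oh=s.is_out_of_home,
                        cluster_id=s.cluster_id,
                        multiply_visited=s.multiply_visited,
                    )
                )
            for m in sd.moves:
                moves.append(
                    dict(
                        participant_id=pw.participant_id,
                        logical_date=d.isoformat(),
                        start=m.start.isoformat(),
                        end=m.end.isoformat(),
                        length_km=m.path_length_km,
                        p90_speed_kmh=m.p90_speed_kmh,
                        mode=m.mode,
                    )
                )
    pd.DataFrame(stops).to_csv(out_dir / "stops.csv", index=False)
    pd.DataFrame(moves).to_csv(out_dir / "moves.csv", index=False)


def write_indicator_matrix(
    matrix: pd.DataFrame, path: str | Path, run_id: int = 0, seed: int = 0
) -> None:
    """Indicator CSV plus a taxonomy sidecar JSON next to it."""
    path = Path(path)
    out = matrix.copy()
    out.insert(0, "run_id", run_id)
    out.insert(1, "seed", seed)
    out.to_csv(path)
    sidecar = path.with_suffix(".taxonomy.json")
    sidecar.write_text(json.dumps(INDICATOR_TAXONOMY, indent=2))


def descriptive_stats(matrix: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean / median / SD per weekly indicator."""
    return pd.DataFrame(
        {
            "mean": matrix.mean(),
            "median": matrix.median(),
            "sd": matrix.std(ddof=1),
        }
    ).loc[list(INDICATOR_NAMES)]
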