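"""The 20 mobility indicators: geometry oracles, durations, aggregation."""

import math
from datetime import date, timedelta

import numpy as np
import pytest

from mobispace.indicators import (
    DAY_SELECTION_SCHEME,
    INDICATOR_NAMES,
    INDICATOR_TAXONOMY,
    aggregate_week,
    bearing_max_dist,
    circular_sd,
    compute_daily_indicators,
    convex_hull,
    entropy,
    grav_compact,
    loc_var,
    maj2min,
    max_dist,
    num_loc,
    num_uniq_loc,
    revisited_ls,
    sde,
    timing_indicators,
    toh,
    trip_indicators,
)
from mobispace.segmentation import StopSegment, annotate_oh, cluster_stops, segment_day
from mobispace.trajectory import project_local

from conftest import BASE, ORIGIN, day_from_points, fix_at


def _shoelace(xy):
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _stop(cluster, minutes, oh=True, t0=0.0):
    a = BASE + timedelta(seconds=t0)
    return StopSegment(
        center_lat=ORIGIN.lat, center_lon=ORIGIN.lon,
        arrival=a, departure=a + timedelta(minutes=minutes),
        member_fixes=[], is_out_of_home=oh, cluster_id=cluster,
    )


class TestHull:
    def test_unit_square(self):
        xy = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        h = convex_hull(xy)
        assert h.area_km2 == pytest.approx(1.0)
        assert h.perimeter_km == pytest.approx(4.0)

    def test_collinear_is_degenerate(self):
        h = convex_hull(np.array([[0, 0], [1, 1], [2, 2]], float))
        assert h.area_km2 == 0.0
        assert h.perimeter_km == pytest.approx(2 * math.hypot(2, 2))

    def test_single_point(self):
        h = convex_hull(np.array([[3.0, 4.0]]))
        assert h.area_km2 == 0.0 and h.perimeter_km == 0.0

    def test_matches_shoelace_oracle_on_random_clouds(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            xy = rng.normal(size=(50, 2)) * rng.uniform(0.5, 5)
            h = convex_hull(xy)
            verts = np.asarray(h.polygon.exterior.coords)[:-1]
            assert h.area_km2 == pytest.approx(_shoelace(verts), rel=1e-9)


class TestSde:
    def test_isotropic_cloud(self):
        rng = np.random.default_rng(12)
        xy = rng.normal(scale=2.0, size=(4000, 2))
        e = sde(xy)
        assert e.semi_major_km == pytest.approx(2.0, rel=0.1)
        assert e.semi_minor_km == pytest.approx(2.0, rel=0.1)
        assert e.area_km2 == pytest.approx(math.pi * e.semi_major_km * e.semi_minor_km)

    def test_collinear_missing(self):
        assert sde(np.array([[0, 0], [1, 1], [2, 2]], float)) is None
        assert sde(np.array([[0, 0], [1, 1]], float)) is None

    def test_orientation_of_45_degree_cloud(self):
        rng = np.random.default_rng(13)
        t = rng.normal(scale=3.0, size=2000)
        n = rng.normal(scale=0.3, size=2000)
        xy = np.column_stack([t / np.sqrt(2) - n / np.sqrt(2), t / np.sqrt(2) + n / np.sqrt(2)])
        e = sde(xy)
        assert e.orientation_rad == pytest.approx(math.pi / 4, abs=0.05)
        assert e.semi_major_km / e.semi_minor_km == pytest.approx(10.0, rel=0.15)

    def test_matches_eigen_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            xy = rng.normal(size=(40, 2)) @ rng.normal(size=(2, 2)) + rng.normal(size=2)
            e = sde(xy)
            if e is None:
                continue
            evals = np.sort(np.linalg.eigvalsh(np.cov(xy, rowvar=False, ddof=1)))
            assert e.semi_minor_km == pytest.approx(math.sqrt(evals[0]), rel=1e-9)
            assert e.semi_major_km == pytest.approx(math.sqrt(evals[1]), rel=1e-9)


class TestScalarGeometry:
    def test_max_dist(self):
        assert max_dist([fix_at(0, 0, 0)], ORIGIN) == pytest.approx(0.0, abs=1e-9)
        assert max_dist([fix_at(0, 0, 1)], ORIGIN) == pytest.approx(1.0, abs=1e-6)
        fixes = [fix_at(i, x, 0) for i, x in enumerate((0.2, 1.5, 0.7))]
        assert max_dist(fixes, ORIGIN) == pytest.approx(1.5, abs=1e-6)

    def test_loc_var_floor_and_scaling(self):
        same = np.zeros((10, 2))
        assert loc_var(same) == pytest.approx(math.log(1e-6), abs=1e-9)
        rng = np.random.default_rng(15)
        xy = rng.normal(size=(500, 2))
        lv1 = loc_var(xy)
        lv2 = loc_var(2 * xy)
        assert lv2 - lv1 == pytest.approx(math.log(4), abs=1e-3)

    def test_grav_compact_known_shapes(self):
        square = convex_hull(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        assert grav_compact(square) == pytest.approx(2 / math.sqrt(math.pi), rel=1e-12)
        th = np.arange(6) * math.pi / 3
        hexagon = convex_hull(np.column_stack([np.cos(th), np.sin(th)]))
        assert grav_compact(hexagon) == pytest.approx(
            6 / (2 * math.sqrt(math.pi * 3 * math.sqrt(3) / 2)), rel=1e-9
        )

    def test_grav_compact_at_least_one(self):
        rng = np.random.default_rng(16)
        for _ in range(50):
            h = convex_hull(rng.normal(size=(30, 2)))
            assert grav_compact(h) >= 1.0
        th = np.linspace(0, 2 * math.pi, 512, endpoint=False)
        circle = convex_hull(np.column_stack([np.cos(th), np.sin(th)]))
        assert grav_compact(circle) == pytest.approx(1.0, abs=1e-3)

    def test_maj2min(self):
        rng = np.random.default_rng(17)
        xy = rng.normal(size=(3000, 2)) * (2.0, 1.0)
        assert maj2min(sde(xy)) == pytest.approx(2.0, rel=0.1)
        iso = rng.normal(size=(3000, 2))
        assert maj2min(sde(iso)) == pytest.approx(1.0, rel=0.1)
        assert maj2min(None) is None


class TestDurationsCounts:
    def test_trip_indicators(self):
        day = day_from_points(
            [(i * 30, 5 * i * 30 / 3600, 0) for i in range(60)]  # 30 min at 5 km/h
        )
        from mobispace.segmentation import extract_moves

        active, _ = extract_moves(day, [], [])
        day2 = day_from_points(
            [(i * 30, 40 * i * 30 / 3600, 0) for i in range(40)]  # 20 min at 40 km/h
        )
        passive, _ = extract_moves(day2, [], [])
        out = trip_indicators(active + passive)
        assert out["DurATM"] == pytest.approx(29.5, abs=0.01)
        assert out["DurPTM"] == pytest.approx(19.5, abs=0.01)
        assert out["MaxDurATM"] == out["DurATM"]
        lengths = [m.path_length_km for m in active + passive]
        assert out["LengthPerTrip"] == pytest.approx(float(np.mean(lengths)))

    def test_trip_indicators_empty(self):
        out = trip_indicators([])
        assert out["LengthPerTrip"] is None
        assert out["DurPTM"] == 0.0 and out["DurATM"] == 0.0 and out["MaxDurATM"] == 0.0

    def test_toh_counts_oh_intervals(self):
        fixes = [fix_at(i * 60, 1.0, 0) for i in range(121)]  # 10:00-12:00 OH at 1/min
        oh = np.ones(121, bool)
        assert toh(fixes, oh) == pytest.approx(120.0)

    def test_toh_all_home_is_zero(self):
        fixes = [fix_at(i * 60, 0, 0) for i in range(100)]
        assert toh(fixes, np.zeros(100, bool)) == 0.0

    def test_toh_skips_long_gaps(self):
        fixes = [fix_at(i * 60, 1, 0) for i in range(10)]
        fixes += [fix_at(9 * 60 + 90 * 60 + i * 60, 1, 0) for i in range(10)]
        oh = np.ones(len(fixes), bool)
        assert toh(fixes, oh) == pytest.approx(18.0)  # two 9-min blocks, gap dropped

    def test_entropy_formulas(self):
        assert entropy([_stop(0, 60)]) == 0.0
        two = [_stop(0, 30), _stop(1, 30)]
        assert entropy(two) == pytest.approx(math.log(2), rel=1e-12)
        three = [_stop(0, 60), _stop(1, 30), _stop(2, 30)]
        assert entropy(three) == pytest.approx(1.5 * math.log(2), rel=1e-12)

    def test_num_loc_counts_visits(self):
        stops = [_stop(0, 30, oh=False), _stop(1, 30), _stop(1, 20), _stop(2, 10)]
        assert num_loc(stops) == 3  # same cluster visited twice counts twice

    def test_num_uniq_loc_counts_clusters(self):
        stops = [_stop(0, 30, oh=False), _stop(1, 30), _stop(1, 20), _stop(2, 10)]
        assert num_uniq_loc(stops) == 2
        assert num_uniq_loc([_stop(0, 30, oh=False)]) == 0
        singles = [_stop(i, 10) for i in range(5)]
        assert num_uniq_loc(singles) == 5


class TestRevisited:
    def _hulls(self, squares):
        out = {}
        for i, (x0, y0, w) in enumerate(squares):
            xy = np.array([[x0, y0], [x0 + w, y0], [x0 + w, y0 + w], [x0, y0 + w]], float)
            out[date(2023, 5, 1) + timedelta(days=i)] = convex_hull(xy)
        return out

    def test_identical_hulls(self):
        rev, avg = revisited_ls(self._hulls([(0, 0, 1)] * 3))
        assert all(v == pytest.approx(1.0) for v in rev.values())
        assert all(v == pytest.approx(1.0) for v in avg.values())

    def test_disjoint_hulls(self):
        rev, avg = revisited_ls(self._hulls([(0, 0, 1), (5, 5, 1), (10, 0, 1)]))
        assert all(v == pytest.approx(0.0) for v in rev.values())

    def test_half_overlap(self):
        # others' union covers the right half of day 0's unit square
        hulls = self._hulls([(0, 0, 1), (0.5, 0, 1)])
        rev, avg = revisited_ls(hulls)
        d0 = date(2023, 5, 1)
        assert rev[d0] == pytest.approx(0.5, rel=1e-9)
        assert avg[d0] == pytest.approx(0.5, rel=1e-9)


class TestCircular:
    def test_bearing_cardinal_directions(self):
        assert bearing_max_dist([fix_at(0, 0, 1)], ORIGIN) == pytest.approx(0.0, abs=1e-6)
        assert bearing_max_dist([fix_at(0, 1, 0)], ORIGIN) == pytest.approx(math.pi / 2, abs=1e-6)
        assert bearing_max_dist([fix_at(0, 0, -1)], ORIGIN) == pytest.approx(math.pi, abs=1e-6)

    def test_bearing_matches_planar_atan2(self):
        rng = np.random.default_rng(18)
        for _ in range(30):
            x, y = rng.uniform(-50, 50, 2)
            f = fix_at(0, x, y)
            b = bearing_max_dist([f], ORIGIN)
            assert b == pytest.approx(math.atan2(x, y) % (2 * math.pi), abs=1e-3)

    def test_bearing_at_home_missing(self):
        assert bearing_max_dist([fix_at(0, 0, 0)], ORIGIN) is None

    def test_circular_sd_values(self):
        assert circular_sd([1.0, 1.0, 1.0]) == pytest.approx(0.0, abs=1e-6)
        assert circular_sd([0.0, math.pi / 2]) == pytest.approx(math.sqrt(math.log(2)), rel=1e-12)
        assert circular_sd([0.0, math.pi]) is None  # antipodal: undefined

    def test_circular_sd_wraparound_insensitive(self):
        a = circular_sd([0.1, 2 * math.pi - 0.1])
        b = circular_sd([-0.1, 0.1])
        assert a == pytest.approx(b, rel=1e-9)


class TestTiming:
    def _segday(self):
        pts = [(i * 60, 0, 0) for i in range(30)]  # home 03:00-03:30
        # walk out 10:00, 2 km away until 11:00, return, afternoon trip 19:00
        pts += [(7 * 3600 + i * 30, 4 * i * 30 / 3600, 0) for i in range(60)]
        pts += [(7.5 * 3600 + i * 60, 2.0, 0) for i in range(60)]
        pts += [(8.5 * 3600 + i * 30, 2.0 - 4 * i * 30 / 3600, 0) for i in range(60)]
        pts += [(9 * 3600 + i * 60, 0, 0) for i in range(7 * 60)]
        pts += [(16 * 3600 + i * 30, 4 * i * 30 / 3600, 0) for i in range(30)]
        seg = segment_day(day_from_points(pts))
        annotate_oh(seg, ORIGIN)
        return seg

    def test_time_max_dist(self):
        seg = self._segday()
        out = timing_indicators(seg, ORIGIN)
        # farthest point reached at ~10:30, i.e. ~450 min after 3 AM
        assert out["TimeMaxDist"] == pytest.approx(450, abs=10)

    def test_time_first_move(self):
        seg = self._segday()
        out = timing_indicators(seg, ORIGIN)
        assert out["TimeFirstMove"] == pytest.approx(420, abs=5)  # 10:00

    def test_period_codes(self):
        seg = self._segday()
        # 2 morning activities (out-trip + OH stop), 1 evening: morning day
        out = timing_indicators(seg, ORIGIN)
        assert out["TimePeriodActive"] == 1.0

    def test_neutral_when_balanced(self):
        # one morning and one evening activity, assembled directly
        from mobispace.segmentation import SegmentedDay
        from mobispace.trajectory import DayTrajectory

        day = DayTrajectory(BASE.date(), [fix_at(0, 0, 0)])
        seg = segment_day(day_from_points([(i * 60, 0, 0) for i in range(20)]))
        morning = self._segday().moves[0]
        evening_fixes = [fix_at(16 * 3600 + i * 30, 4 * i * 30 / 3600, 0) for i in range(20)]
        from mobispace.segmentation import MoveSegment

        evening = MoveSegment(
            member_fixes=evening_fixes,
            start=evening_fixes[0].timestamp,
            end=evening_fixes[-1].timestamp,
            path_length_km=1.0,
            p90_speed_kmh=4.0,
            mode="active",
        )
        balanced = SegmentedDay(day=day, stops=[], moves=[morning, evening], jump_fixes=[])
        annotate_oh(balanced, ORIGIN)
        out = timing_indicators(balanced, ORIGIN)
        assert out["TimePeriodActive"] == 2.0


class TestAggregateWeek:
    def _daily(self, values_by_name):
        days = [date(2023, 5, 1) + timedelta(days=i) for i in range(3)]
        daily = {d: {} for d in days}
        for name, vals in values_by_name.items():
            for d, v in zip(days, vals):
                daily[d][name] = v
        return daily, days

    def test_median_circular_mean_rules(self):
        daily, days = self._daily(
            {
                "TOH": [100.0, 200.0, 400.0],
                "TimePeriodActive": [1.0, 2.0, 3.0],
                "SDDirMaxDist": [0.0, math.pi / 2, math.pi / 4],
            }
        )
        week = aggregate_week(daily, r_days=days, m_days=days)
        assert week["TOH"] == 200.0
        assert week["TimePeriodActive"] == pytest.approx(2.0)
        # circular SD of {0, pi/2, pi/4}: Rbar = (1 + sqrt(2))/3
        rbar = (1 + math.sqrt(2)) / 3
        assert week["SDDirMaxDist"] == pytest.approx(math.sqrt(-2 * math.log(rbar)), rel=1e-9)

    def test_schemes_use_their_days(self):
        days = [date(2023, 5, 1) + timedelta(days=i) for i in range(4)]
        daily = {d: {"TOH": 100.0 + i, "GravCompact": 1.0 + i} for i, d in enumerate(days)}
        week = aggregate_week(daily, r_days=days[:2], m_days=days[2:])
        assert week["TOH"] == pytest.approx(100.5)  # R days only
        assert week["GravCompact"] == pytest.approx(3.5)  # M days only

    def test_missing_propagation(self):
        daily, days = self._daily({"SDE": [None, None, None]})
        week = aggregate_week(daily, r_days=days, m_days=days)
        assert math.isnan(week["SDE"])

    def test_week_level_passthrough_and_column_count(self):
        daily, days = self._daily({"TOH": [1.0, 2.0, 3.0]})
        week = aggregate_week(daily, days, days, week_level={"NumUniqLoc": 4.0})
        assert week["NumUniqLoc"] == 4.0
        assert set(week) == set(INDICATOR_NAMES)
        assert len(week) == 20


class TestTaxonomyAndEquivariance:
    def test_taxonomy_covers_all_indicators(self):
        assert set(INDICATOR_TAXONOMY) == set(INDICATOR_NAMES)
        for tags in INDICATOR_TAXONOMY.values():
            assert tags["day_selection"] in ("R", "M")
            assert tags["temporal_scale"] == "global"

    def test_daily_indicators_scale_equivariance(self):
        """Doubling all distances scales lengths x2, areas x4, leaves
        shape/timing/entropy invariant."""

        def build(scale):
            rng = np.random.default_rng(19)
            pts = [(i * 60, 0, 0) for i in range(20)]
            pts += [(5 * 3600 + i * 30, scale * 5 * i * 30 / 3600, scale * 0.2) for i in range(60)]
            pts += [(6 * 3600 + i * 60 + 1800, scale * 2.5, scale * (0.2 + 0.01 * rng.standard_normal())) for i in range(60)]
            pts += [(8 * 3600 + i * 60, scale * 1.0, -scale * 0.5) for i in range(40)]
            seg = segment_day(day_from_points(pts))
            annotate_oh(seg, ORIGIN)
            cluster_stops([s for s in seg.stops])
            return compute_daily_indicators(seg, ORIGIN)

        base = build(1.0)
        doubled = build(2.0)
        assert doubled["MaxDist"] == pytest.approx(2 * base["MaxDist"], rel=1e-3)
        assert doubled["CHull"] == pytest.approx(4 * base["CHull"], rel=1e-2)
        assert doubled["GravCompact"] == pytest.approx(base["GravCompact"], rel=1e-2)
        assert doubled["TimePeriodActive"] == base["TimePeriodActive"]
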