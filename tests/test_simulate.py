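import numpy as np
import pandas as pd
import pytest

from crowdcontact.geometry import haversine_m
from crowdcontact.ingestion import filter_bounds
from crowdcontact.records import day_number, write_daily_files
from crowdcontact.simulate import (
    GatheringConfig,
    GatheringPlan,
    generate_records,
    inject_defects,
    plan_gatherings,
)

START = day_number(__import__("datetime").date(2020, 1, 1))


def _records(world, plans=(), days=1, seed=0, **kw):
    kw.setdefault("daily_activity", 1.0)
    return generate_records(world, list(plans), days, start_day=START, seed=seed, **kw)


class TestGenerateRecords:
    def test_mean_cadence_per_reporting_user(self):
        # feed cadence: ~120 records/user/day, i.e. one every ~12 minutes
        from crowdcontact.world import WorldConfig, generate_world

        world = generate_world(WorldConfig(n_users=1000), seed=2)
        frame = _records(world, days=1, seed=3)
        per_user = len(frame) / frame["user_id"].nunique()
        assert per_user == pytest.approx(120.0, rel=0.05)

    def test_deterministic_stream_bytes(self, tiny_world, tmp_path):
        f1 = _records(tiny_world, seed=5)
        f2 = _records(tiny_world, seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_daily_files(f1, d1)
        write_daily_files(f2, d2)
        for p1, p2 in zip(sorted(d1.iterdir()), sorted(d2.iterdir())):
            assert p1.read_bytes() == p2.read_bytes()

    def test_all_records_inside_world(self, tiny_world):
        frame = _records(tiny_world, seed=1)
        assert tiny_world.bounds.contains(frame["lat"], frame["lon"]).all()

    def test_night_records_pinned_to_home(self, tiny_world):
        frame = _records(tiny_world, seed=4)
        homes = {i: (u.home_lat, u.home_lon) for i, u in enumerate(tiny_world.users)}
        local_sec = frame["timestamp"].to_numpy() + tiny_world.default_utc_offset_min * 60
        hour = (local_sec % 86400) // 3600
        night = (hour >= 23) | (hour < 9)
        sub = frame.loc[night]
        hlat = np.array([homes[i][0] for i in sub["user_ix"]])
        hlon = np.array([homes[i][1] for i in sub["user_ix"]])
        d = haversine_m(sub["lat"].to_numpy(), sub["lon"].to_numpy(), hlat, hlon)
        # 10 m Gaussian jitter about the centroid: all within ~6 sigma
        assert np.quantile(d, 0.99) < 40.0
        assert d.max() < 90.0

    def test_planted_gathering_populates_poi(self, tiny_world):
        poi = tiny_world.pois[0]
        users = tuple(u.id for u in tiny_world.users[:15])
        plan = GatheringPlan(poi.id, START, 12 * 60.0, 13 * 60.0, users, spread_m=5.0)
        frame = _records(tiny_world, [plan], seed=6)
        local_sec = frame["timestamp"].to_numpy() + tiny_world.default_utc_offset_min * 60
        in_window = (local_sec % 86400 >= 12 * 3600) & (local_sec % 86400 < 13 * 3600)
        d = haversine_m(frame["lat"].to_numpy(), frame["lon"].to_numpy(), poi.lat, poi.lon)
        n_inside = int((in_window & (d <= poi.radius_m)).sum())
        # 15 users for 60 min at ~1 record/12 min: expect >= half of 75
        assert n_inside >= 15 * 60 / 12 * 0.5

    def test_no_plans_no_poi_pileup(self, tiny_world):
        frame = _records(tiny_world, seed=6)
        local_sec = frame["timestamp"].to_numpy() + tiny_world.default_utc_offset_min * 60
        day_mask = (local_sec % 86400 >= 9 * 3600) & (local_sec % 86400 < 23 * 3600)
        sub = frame.loc[day_mask]
        for poi in tiny_world.pois:
            d = haversine_m(sub["lat"].to_numpy(), sub["lon"].to_numpy(), poi.lat, poi.lon)
            inside = int((d <= poi.radius_m).sum())
            # uniform background only: disc area / CBG area of that day's records
            assert inside < 0.01 * len(sub)

    def test_unknown_user_or_poi_rejected(self, tiny_world):
        with pytest.raises(KeyError):
            _records(tiny_world, [GatheringPlan("nope", START, 600.0, 660.0, ("u00000",), 5.0)])
        with pytest.raises(KeyError):
            _records(
                tiny_world,
                [GatheringPlan(tiny_world.pois[0].id, START, 600.0, 660.0, ("ghost",), 5.0)],
            )

    def test_spread_wider_than_poi_rejected(self, tiny_world):
        poi = tiny_world.pois[0]
        plan = GatheringPlan(poi.id, START, 600.0, 660.0, (tiny_world.users[0].id,), poi.radius_m + 1)
        with pytest.raises(ValueError):
            _records(tiny_world, [plan])

    def test_bad_cadence_rejected(self, tiny_world):
        with pytest.raises(ValueError):
            _records(tiny_world, cadence_per_day=0.0)


class TestDailyActivity:
    def test_profile_thins_the_panel(self, tiny_world):
        full = _records(tiny_world, seed=9, daily_activity=1.0)
        half = _records(tiny_world, seed=9, daily_activity=0.5)
        assert half["user_id"].nunique() < full["user_id"].nunique()
        # cadence per reporting user unchanged
        assert len(half) / half["user_id"].nunique() == pytest.approx(
            len(full) / full["user_id"].nunique(), rel=0.05
        )


class TestPlanGatherings:
    def test_disjoint_participants_within_day(self, tiny_world):
        plans = plan_gatherings(
            tiny_world,
            start_day=START,
            days=2,
            seed=0,
            config=GatheringConfig(participants=(5, 8)),
            exact_per_day=3,
        )
        by_day = {}
        for p in plans:
            by_day.setdefault(p.day, []).append(p)
        for day, group in by_day.items():
            seen = set()
            pois = set()
            for p in group:
                assert not (set(p.user_ids) & seen)
                seen |= set(p.user_ids)
                pois.add(p.poi_id)
            assert len(pois) == len(group)


class TestInjectDefects:
    def test_identity_at_zero_fractions(self, tiny_world):
        frame = _records(tiny_world, seed=1)
        out = inject_defects(frame, 0.0, 0.0, seed=0, world=tiny_world)
        pd.testing.assert_frame_equal(out.records, frame)
        assert out.late_index.size == 0 and out.oob_index.size == 0

    def test_exact_late_count_next_day(self, tiny_world):
        frame = _records(tiny_world, seed=1)
        out = inject_defects(frame, 0.005, 0.0, seed=0, late_tail=0.0, world=tiny_world)
        n_late = int(round(0.005 * len(frame)))
        moved = out.records["arrival_day"] != frame["arrival_day"]
        assert int(moved.sum()) == n_late
        assert (
            out.records.loc[moved, "arrival_day"] == frame.loc[moved, "arrival_day"] + 1
        ).all()

    def test_oob_records_fail_bounds_filter(self, tiny_world):
        frame = _records(tiny_world, seed=1)
        out = inject_defects(frame, 0.0, 0.01, seed=0, world=tiny_world)
        kept, dropped = filter_bounds(out.records, tiny_world.bounds)
        assert len(dropped) == int(round(0.01 * len(frame)))
        assert set(dropped.index) == set(out.oob_index)

    def test_bad_fraction_rejected(self, tiny_world):
        frame = _records(tiny_world, seed=1)
        with pytest.raises(ValueError):
            inject_defects(frame, 1.0, 0.0, seed=0, world=tiny_world)
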