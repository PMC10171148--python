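import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crowdcontact.ingestion import clean_frame
from crowdcontact.records import day_number, split_by_arrival
from crowdcontact.simulate import generate_records
from crowdcontact.weighting import (
    infer_home_cbgs,
    monthly_weights,
    persons_per_user,
    weekend_night_mask,
    winsorize,
)

FRI = day_number(dt.date(2020, 1, 3))  # Friday
SAT, SUN, MON = FRI + 1, FRI + 2, FRI + 3


class TestWeekendNightWindow:
    @pytest.mark.parametrize(
        "day,hour,expected",
        [
            (FRI, 23, True),   # Friday 23:xx
            (SAT, 3, True),    # Saturday small hours
            (SAT, 8, True),    # Saturday 08:59 side
            (SAT, 23, True),   # Saturday 23:xx
            (SUN, 0, True),    # Sunday small hours
            (SUN, 8, True),
            (SUN, 23, False),  # Sunday night belongs to the work week
            (FRI, 22, False),  # before 11 pm
            (SAT, 9, False),   # 9 am sharp is out
            (SAT, 12, False),  # daytime
            (MON, 2, False),   # Monday small hours
        ],
    )
    def test_window_membership(self, day, hour, expected):
        assert bool(weekend_night_mask(np.array([day]), np.array([hour]))[0]) is expected


def _frame(tiny_world, rows):
    """rows: (user_id, cbg_ix, local_day, local_hour)."""
    offset = tiny_world.default_utc_offset_min
    recs = []
    for uid, cbg_ix, day, hour in rows:
        ts = day * 86400 + hour * 3600 + 600 - offset * 60
        recs.append((uid, ts, cbg_ix, day))
    return pd.DataFrame(recs, columns=["user_id", "timestamp", "cbg_ix", "local_day"])


class TestHomeInference:
    def test_single_cbg_user(self, tiny_world):
        frame = _frame(tiny_world, [("u1", 0, SAT, 3)] * 4)
        homes = infer_home_cbgs(frame, tiny_world)
        assert homes.loc["u1", "home_cbg"] == tiny_world.cbg_ids[0]
        assert homes.loc["u1", "n_night_records"] == 4

    def test_modal_cbg_wins(self, tiny_world):
        rows = [("u1", 0, SAT, 3)] * 3 + [("u1", 1, SAT, 4)] * 5
        homes = infer_home_cbgs(_frame(tiny_world, rows), tiny_world)
        assert homes.loc["u1", "home_cbg"] == tiny_world.cbg_ids[1]

    def test_tie_broken_by_total_records_then_id(self, tiny_world):
        # equal night counts; cbg 1 has more all-hours records
        rows = (
            [("u1", 0, SAT, 3)] * 4
            + [("u1", 1, SAT, 4)] * 4
            + [("u1", 1, MON, 12)] * 3
        )
        homes = infer_home_cbgs(_frame(tiny_world, rows), tiny_world)
        assert homes.loc["u1", "home_cbg"] == tiny_world.cbg_ids[1]
        # full tie: smaller CBG id
        rows = [("u2", 2, SAT, 3)] * 4 + [("u2", 1, SAT, 4)] * 4
        homes = infer_home_cbgs(_frame(tiny_world, rows), tiny_world)
        assert homes.loc["u2", "home_cbg"] == tiny_world.cbg_ids[1]

    def test_user_without_night_records_excluded(self, tiny_world):
        homes = infer_home_cbgs(_frame(tiny_world, [("u1", 0, MON, 12)]), tiny_world)
        assert "u1" not in homes.index


class TestPersonsPerUser:
    def test_population_split_evenly(self):
        homes = pd.DataFrame(
            {"home_cbg": ["g"] * 20, "n_night_records": 1},
            index=pd.Index([f"u{i}" for i in range(20)], name="user_id"),
        )
        out = persons_per_user(homes, {"g": 1000})
        assert (out["raw"] == 50.0).all()

    def test_single_user_carries_whole_cbg(self):
        homes = pd.DataFrame(
            {"home_cbg": ["g"], "n_night_records": 1},
            index=pd.Index(["u0"], name="user_id"),
        )
        out = persons_per_user(homes, {"g": 500})
        assert out["raw"].iloc[0] == 500.0

    def test_missing_census_cbg_raises(self):
        homes = pd.DataFrame(
            {"home_cbg": ["g"], "n_night_records": 1},
            index=pd.Index(["u0"], name="user_id"),
        )
        with pytest.raises(KeyError):
            persons_per_user(homes, {"other": 100})

    def test_zero_population_raises(self):
        homes = pd.DataFrame(
            {"home_cbg": ["g"], "n_night_records": 1},
            index=pd.Index(["u0"], name="user_id"),
        )
        with pytest.raises(ValueError):
            persons_per_user(homes, {"g": 0})

    def test_population_conservation_per_cbg(self, rng):
        cbgs = [f"g{k}" for k in range(5)]
        census = {g: int(p) for g, p in zip(cbgs, rng.integers(100, 2000, 5))}
        users = [f"u{i}" for i in range(300)]
        homes = pd.DataFrame(
            {"home_cbg": rng.choice(cbgs, 300), "n_night_records": 1},
            index=pd.Index(users, name="user_id"),
        )
        out = persons_per_user(homes, census)
        sums = out.groupby("home_cbg")["raw"].sum()
        for g, total in sums.items():
            assert total == pytest.approx(census[g], rel=1e-12)


class TestWinsorize:
    def test_degenerate_distribution_unchanged(self):
        v = np.full(10, 3.5)
        np.testing.assert_array_equal(winsorize(v), v)

    def test_uniform_1_to_100_against_percentile_oracle(self):
        v = np.arange(1.0, 101.0)
        out = winsorize(v)
        lo, hi = np.percentile(v, [5, 95])  # sort-based oracle
        assert out.min() == pytest.approx(lo)
        assert out.max() == pytest.approx(hi)
        assert lo == pytest.approx(5.0, abs=1.0) and hi == pytest.approx(95.0, abs=1.0)

    @given(
        st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=1, max_size=200)
    )
    def test_monotone_and_count_preserving(self, values):
        v = np.array(values)
        out = winsorize(v)
        assert out.size == v.size
        order = np.argsort(v, kind="stable")
        assert (np.diff(out[order]) >= -1e-12).all()
        lo, hi = np.percentile(v, [5, 95])
        assert (out >= lo - 1e-9).all() and (out <= hi + 1e-9).all()


class TestSamplingRatioRecovery:
    def test_persons_per_user_recovers_sampling_ratio(self, tiny_world_config):
        # users drawn uniformly from the population: the weights must
        # concentrate near total population / total users (>= 50 users/CBG)
        import dataclasses

        from crowdcontact.world import generate_world

        cfg = dataclasses.replace(tiny_world_config, n_users=400)
        world = generate_world(cfg, seed=21)
        start = day_number(dt.date(2020, 1, 1))
        records = generate_records(
            world, [], 9, start_day=start, seed=3, daily_activity=1.0
        )
        clean, _ = clean_frame(split_by_arrival(records), world)
        weights = monthly_weights(clean, world)
        true_ratio = world.cbg_populations.sum() / len(world.users)
        assert np.median(weights["winsorized"]) == pytest.approx(true_ratio, rel=0.10)
        assert len(weights) >= 0.95 * len(world.users)
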