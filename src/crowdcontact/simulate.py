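"""Synthetic LBS record streams with planted gatherings and known truth.

The generator emulates the statistical structure of a commercial
location-based-services feed: roughly 120 records per user per day (one
every ~12 minutes on average), positional accuracy of about 10 m,
night-time records pinned to the user's (centroid-obfuscated) home, a
lower sampling rate during sleeping hours, and a small share of records
that arrive a day or more late or carry out-of-bounds coordinates.

Gatherings are planted explicitly: a :class:`GatheringPlan` relocates the
participants' records during a time window to a Gaussian spread about a
POI center, giving every downstream stage a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import METERS_PER_DEG_LAT, Rect, meters_per_deg_lon
from .world import World

#: local hours treated as night (lower sampling rate; records at home)
NIGHT_HOURS = frozenset({23, 0, 1, 2, 3, 4, 5, 6, 7, 8})


def default_daily_activity(day_index: int, weekday: int) -> float:
    """Default daily panel-participation probability.

    Commercial LBS panels churn daily (phones off, travel, opt-outs), and
    the kind of period this pipeline is built for carries large behavioral
    shifts.  The default profile emulates a study month with a mid-period
    intervention: near-full participation for two weeks, a weeklong
    decline to a suppressed plateau, plus a weekly ripple.
    """
    if day_index < 14:
        base = 0.95
    elif day_index < 21:
        base = 0.95 - (0.40 / 7.0) * (day_index - 14)
    else:
        base = 0.55
    ripple = 0.04 * np.sin(2.0 * np.pi * day_index / 7.0)
    return float(np.clip(base + ripple, 0.05, 1.0))


@dataclass(frozen=True)
class GatheringPlan:
    """Ground truth for one planted crowd at one POI on one local day."""

    poi_id: str
    day: int  # local epoch-day
    start_min: float  # local minutes of day
    end_min: float
    user_ids: tuple[str, ...]
    spread_m: float  # std. dev. of participant positions about the POI center

    def __post_init__(self) -> None:
        if self.end_min <= self.start_min:
            raise ValueError("gathering window is empty")
        if len(set(self.user_ids)) != len(self.user_ids):
            raise ValueError("participants must be distinct")


def hourly_weights(night_multiplier: float) -> np.ndarray:
    """Relative record-sampling rate per local hour, night hours damped."""
    w = np.ones(24)
    for h in NIGHT_HOURS:
        w[h] = night_multiplier
    return w


def generate_records(
    world: World,
    plans: Sequence[GatheringPlan],
    days: int,
    *,
    start_day: int,
    cadence_per_day: float = 120.0,
    seed: int = 0,
    night_multiplier: float = 0.5,
    accuracy_mean_m: float = 10.0,
    accuracy_sd_m: float = 2.0,
    home_jitter_m: float = 10.0,
    os_labels: Sequence[str] = ("ios", "android"),
    os_probs: Sequence[float] = (0.45, 0.55),
    daily_activity=None,
) -> pd.DataFrame:
    """Generate the record stream for ``days`` consecutive local days.

    Each user is active on a given day with the probability given by the
    ``daily_activity`` profile (default :func:`default_daily_activity`;
    pass 1.0 for a churn-free panel, or a sequence of per-day values).
    Each active user's record count that day is Poisson with mean
    ``cadence_per_day``; record times follow the diurnal hourly profile.
    Night records sit at the home centroid with ``home_jitter_m`` Gaussian
    jitter, gathering participants sit about their POI during the plan
    window, and all other records scatter uniformly over the user's home
    CBG.  Deterministic for a fixed seed.
    """
    if cadence_per_day <= 0:
        raise ValueError("cadence_per_day must be positive")
    if days < 1:
        raise ValueError("days must be >= 1")
    user_ids = [u.id for u in world.users]
    user_pos = {uid: i for i, uid in enumerate(user_ids)}
    poi_ids = {p.id for p in world.pois}
    for plan in plans:
        if plan.poi_id not in poi_ids:
            raise KeyError(f"plan references unknown POI {plan.poi_id}")
        for uid in plan.user_ids:
            if uid not in user_pos:
                raise KeyError(f"plan references unknown user {uid}")
        poi = world.poi_by_id(plan.poi_id)
        if plan.spread_m > poi.radius_m:
            raise ValueError(
                f"plan spread {plan.spread_m} m exceeds POI radius {poi.radius_m} m"
            )

    rng = np.random.default_rng(seed)
    n_users = len(user_ids)
    w = hourly_weights(night_multiplier)
    p_hour = w / w.sum()

    arrays = world._arrays()
    home_ix = world.user_home_indices()
    home_lat = np.array([u.home_lat for u in world.users])
    home_lon = np.array([u.home_lon for u in world.users])
    offsets_min = arrays["offset"][home_ix]
    m_per_deg_lon = meters_per_deg_lon(float(np.mean(home_lat)))

    user_os = rng.choice(list(os_labels), size=n_users, p=list(os_probs))

    plans_by_day: dict[int, list[GatheringPlan]] = {}
    for plan in plans:
        plans_by_day.setdefault(plan.day, []).append(plan)

    def _activity(day_index: int, weekday: int) -> float:
        if daily_activity is None:
            return default_daily_activity(day_index, weekday)
        if callable(daily_activity):
            return float(daily_activity(day_index, weekday))
        if np.isscalar(daily_activity):
            return float(daily_activity)
        return float(daily_activity[day_index])

    chunks: list[pd.DataFrame] = []
    night_arr = np.array(sorted(NIGHT_HOURS))
    for d in range(start_day, start_day + days):
        p_active = _activity(d - start_day, int((d + 3) % 7))
        active = rng.random(n_users) < p_active
        counts = np.where(active, rng.poisson(cadence_per_day, size=n_users), 0)
        total = int(counts.sum())
        uix = np.repeat(np.arange(n_users, dtype=np.int32), counts)
        hours = rng.choice(24, size=total, p=p_hour)
        local_sec = hours * 3600.0 + rng.uniform(0.0, 3600.0, size=total)
        off_sec = offsets_min[uix] * 60
        ts = (np.int64(d) * 86400 - off_sec + local_sec).astype(np.int64)

        # default: scattered uniformly over the home CBG
        hix = home_ix[uix]
        lat = rng.uniform(arrays["lat_min"][hix], arrays["lat_max"][hix])
        lon = rng.uniform(arrays["lon_min"][hix], arrays["lon_max"][hix])

        night = np.isin(hours, night_arr)
        n_night = int(night.sum())
        lat[night] = home_lat[uix[night]] + rng.normal(
            0.0, home_jitter_m / METERS_PER_DEG_LAT, size=n_night
        )
        lon[night] = home_lon[uix[night]] + rng.normal(
            0.0, home_jitter_m / m_per_deg_lon, size=n_night
        )

        for plan in plans_by_day.get(d, ()):
            poi = world.poi_by_id(plan.poi_id)
            members = np.array([user_pos[u] for u in plan.user_ids], dtype=np.int32)
            sel = (
                np.isin(uix, members)
                & (local_sec >= plan.start_min * 60.0)
                & (local_sec < plan.end_min * 60.0)
            )
            n_sel = int(sel.sum())
            lat[sel] = poi.lat + rng.normal(0.0, plan.spread_m / METERS_PER_DEG_LAT, size=n_sel)
            lon[sel] = poi.lon + rng.normal(0.0, plan.spread_m / m_per_deg_lon, size=n_sel)

        chunk = pd.DataFrame(
            {
                "user_id": np.array(user_ids, dtype=object)[uix],
                "timestamp": ts,
                "lat": lat,
                "lon": lon,
                "accuracy": np.clip(
                    rng.normal(accuracy_mean_m, accuracy_sd_m, size=total), 2.0, None
                ),
                "os": user_os[uix],
                "arrival_day": np.full(total, d, dtype=np.int64),
                "user_ix": uix,
            }
        )
        order = np.argsort(chunk["timestamp"].to_numpy(), kind="stable")
        chunks.append(chunk.iloc[order].reset_index(drop=True))

    frame = pd.concat(chunks, ignore_index=True)
    frame["user_id"] = frame["user_id"].astype("category")
    frame["os"] = frame["os"].astype("category")
    return frame


@dataclass(frozen=True)
class GatheringConfig:
    """Distributional knobs for :func:`plan_gatherings`."""

    mean_per_day: float = 8.0
    weekly_amplitude: float = 0.5  # sinusoidal day-to-day signal in plan counts
    participants: tuple[int, int] = (12, 24)
    duration_min: tuple[float, float] = (40.0, 90.0)
    spread_m: tuple[float, float] = (3.0, 7.0)
    start_hour: tuple[float, float] = (10.0, 17.0)


def plan_gatherings(
    world: World,
    *,
    start_day: int,
    days: int,
    seed: int,
    config: GatheringConfig = GatheringConfig(),
    exact_per_day: int | None = None,
) -> list[GatheringPlan]:
    """Sample daytime gathering plans at distinct POIs with disjoint
    participant sets within each day.

    ``exact_per_day`` pins the plan count per day (used by recovery
    studies); otherwise the count is Poisson about a weekly sinusoid so the
    daily contact totals carry a genuine temporal signal.
    """
    rng = np.random.default_rng(seed)
    user_ids = [u.id for u in world.users]
    poi_ids = [p.id for p in world.pois]
    plans: list[GatheringPlan] = []
    for k in range(days):
        d = start_day + k
        if exact_per_day is not None:
            n_plans = min(exact_per_day, len(poi_ids))
        else:
            lam = config.mean_per_day * (
                1.0 + config.weekly_amplitude * np.sin(2.0 * np.pi * k / 7.0)
            )
            n_plans = int(min(rng.poisson(max(lam, 0.1)), len(poi_ids)))
        if n_plans == 0:
            continue
        chosen_pois = rng.choice(poi_ids, size=n_plans, replace=False)
        lo_p, hi_p = config.participants
        sizes = rng.integers(lo_p, hi_p + 1, size=n_plans)
        if sizes.sum() > len(user_ids):
            raise ValueError("not enough users for disjoint gathering participants")
        pool = rng.permutation(len(user_ids))
        cursor = 0
        for poi_id, size in zip(chosen_pois, sizes):
            members = tuple(user_ids[i] for i in pool[cursor : cursor + size])
            cursor += size
            start = rng.uniform(*config.start_hour) * 60.0
            dur = rng.uniform(*config.duration_min)
            spread = rng.uniform(*config.spread_m)
            plans.append(
                GatheringPlan(
                    poi_id=str(poi_id),
                    day=d,
                    start_min=float(start),
                    end_min=float(start + dur),
                    user_ids=members,
                    spread_m=float(spread),
                )
            )
    return plans


@dataclass
class DefectInjection:
    """Records with injected feed defects, plus the planted truth."""

    records: pd.DataFrame
    late_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    oob_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))


def inject_defects(
    records: pd.DataFrame,
    late_fraction: float,
    oob_fraction: float,
    seed: int,
    *,
    late_tail: float = 0.0,
    tail_geom_p: float = 0.5,
    bounds: Rect | None = None,
    world: World | None = None,
) -> DefectInjection:
    """Inject late-arriving and out-of-bounds records.

    ``round(late_fraction * n)`` records get ``arrival_day`` pushed to the
    next day; a ``late_tail`` share of those are pushed further by a
    geometric number of extra days.  ``round(oob_fraction * n)`` records
    (disjoint from the late set) get coordinates outside the world bounds.
    Positional row indices of both defect sets are returned for tests.
    """
    for frac in (late_fraction, oob_fraction):
        if not (0.0 <= frac < 1.0):
            raise ValueError("defect fractions must lie in [0, 1)")
    out = records.copy()
    n = len(out)
    n_late = int(round(late_fraction * n))
    n_oob = int(round(oob_fraction * n))
    if n_late + n_oob == 0:
        return DefectInjection(records=out)
    if bounds is None:
        if world is None:
            raise ValueError("need bounds or world to place out-of-bounds records")
        bounds = world.bounds

    rng = np.random.default_rng(seed)
    picks = rng.choice(n, size=n_late + n_oob, replace=False)
    late_ix = np.sort(picks[:n_late])
    oob_ix = np.sort(picks[n_late:])

    if n_late:
        extra = np.zeros(n_late, dtype=np.int64)
        tail_sel = rng.random(n_late) < late_tail
        extra[tail_sel] = rng.geometric(tail_geom_p, size=int(tail_sel.sum()))
        arrival = out["arrival_day"].to_numpy().copy()
        arrival[late_ix] += 1 + extra
        out["arrival_day"] = arrival

    if n_oob:
        lat = out["lat"].to_numpy().copy()
        lon = out["lon"].to_numpy().copy()
        side = rng.integers(0, 4, size=n_oob)
        bump = rng.uniform(0.5, 3.0, size=n_oob)
        lat[oob_ix[side == 0]] = bounds.lat_max + bump[side == 0]
        lat[oob_ix[side == 1]] = bounds.lat_min - bump[side == 1]
        lon[oob_ix[side == 2]] = bounds.lon_max + bump[side == 2]
        lon[oob_ix[side == 3]] = bounds.lon_min - bump[side == 3]
        out["lat"] = lat
        out["lon"] = lon

    return DefectInjection(records=out, late_index=late_ix, oob_index=oob_ix)
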