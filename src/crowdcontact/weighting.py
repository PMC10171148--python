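"""Population-size weighting: from observed users to estimated persons.

App users are a geographically biased sample of the population.  Each
user's home CBG is inferred monthly from where their weekend-night records
fall (after 11 pm and before 9 am local time on the Friday->Saturday and
Saturday->Sunday nights); the user then represents
``population(home CBG) / users observed from that CBG`` real persons that
month.  Weights are winsorized at the 5th/95th percentiles of the run's
user population so a CBG with two observed users cannot dominate the
contact estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .records import weekday_of_day
from .world import World

FRIDAY, SATURDAY, SUNDAY = 4, 5, 6


@dataclass(frozen=True)
class HomeAssignment:
    user_id: str
    month: str  # "YYYY-MM"
    home_cbg: str
    n_night_records: int


@dataclass(frozen=True)
class UserWeight:
    user_id: str
    month: str
    raw: float
    winsorized: float


def weekend_night_mask(local_day: np.ndarray, local_hour: np.ndarray) -> np.ndarray:
    """True for records in [23:00, 24:00) of a Friday/Saturday or
    [00:00, 09:00) of a Saturday/Sunday, local time."""
    wd = weekday_of_day(local_day)
    late = (local_hour == 23) & ((wd == FRIDAY) | (wd == SATURDAY))
    early = (local_hour < 9) & ((wd == SATURDAY) | (wd == SUNDAY))
    return late | early


def _local_hour(frame: pd.DataFrame, world: World) -> np.ndarray:
    offsets = world.cbg_offsets_min[frame["cbg_ix"].to_numpy()]
    local_sec = frame["timestamp"].to_numpy() + offsets * 60
    return ((local_sec % 86400) // 3600).astype(np.int64)


def infer_home_cbgs(frame: pd.DataFrame, world: World) -> pd.DataFrame:
    """Modal weekend-night CBG per user over one month of cleaned records.

    ``frame`` must carry ``cbg_ix`` and ``local_day``.  Users with no
    weekend-night records get no assignment.  Ties: larger night count,
    then larger all-hours record count, then smaller CBG id.
    Returns a frame indexed by user_id with columns home_cbg and
    n_night_records.
    """
    if len(frame) == 0:
        return pd.DataFrame(columns=["home_cbg", "n_night_records"])
    hour = _local_hour(frame, world)
    night = weekend_night_mask(frame["local_day"].to_numpy(), hour)

    pairs_all = (
        frame.groupby(["user_id", "cbg_ix"], observed=True).size().rename("n_total")
    )
    pairs_night = (
        frame.loc[night]
        .groupby(["user_id", "cbg_ix"], observed=True)
        .size()
        .rename("n_night")
    )
    tab = pd.concat([pairs_night, pairs_all], axis=1).fillna(0).reset_index()
    tab = tab.loc[tab["n_night"] > 0]
    if len(tab) == 0:
        return pd.DataFrame(columns=["home_cbg", "n_night_records"])
    ids = np.array(world.cbg_ids, dtype=object)
    tab["cbg_id"] = ids[tab["cbg_ix"].to_numpy(dtype=int)]
    tab = tab.sort_values(
        ["user_id", "n_night", "n_total", "cbg_id"],
        ascending=[True, False, False, True],
    )
    best = tab.groupby("user_id", observed=True).head(1)
    out = best.set_index("user_id")[["cbg_id", "n_night"]]
    out.columns = ["home_cbg", "n_night_records"]
    out["n_night_records"] = out["n_night_records"].astype(int)
    return out


def persons_per_user(homes: pd.DataFrame, census: Mapping[str, int] | pd.Series) -> pd.DataFrame:
    """Raw persons-per-user weights from home assignments and census.

    Every user from CBG g weighs population(g) / (users whose home is g),
    so the weights over a CBG sum back to its census population exactly.
    """
    if len(homes) == 0:
        return pd.DataFrame(columns=["home_cbg", "raw"])
    census = pd.Series(census)
    counts = homes.groupby("home_cbg", observed=True).size()
    missing = [g for g in counts.index if g not in census.index]
    if missing:
        raise KeyError(f"home CBGs missing from census: {missing}")
    bad = [g for g in counts.index if census[g] <= 0]
    if bad:
        raise ValueError(f"CBGs with users but non-positive census population: {bad}")
    per_user = census.loc[counts.index].astype(float) / counts
    out = homes[["home_cbg"]].copy()
    out["raw"] = per_user.loc[out["home_cbg"]].to_numpy()
    return out


def winsorize(values, lower: float = 5.0, upper: float = 95.0) -> np.ndarray:
    """Clamp to the [lower, upper] percentiles (linear interpolation)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v
    lo, hi = np.percentile(v, [lower, upper])
    return np.clip(v, lo, hi)


def monthly_weights(
    frame: pd.DataFrame,
    world: World,
    *,
    lower: float = 5.0,
    upper: float = 95.0,
) -> pd.DataFrame:
    """Winsorized persons-per-user for every month present in ``frame``.

    Returns a frame with columns month, user_id, home_cbg, raw, winsorized.
    Percentiles are computed over all assigned users within each month of
    the processed region.
    """
    if len(frame) == 0:
        return pd.DataFrame(columns=["month", "user_id", "home_cbg", "raw", "winsorized"])
    day = frame["local_day"].to_numpy()
    month = pd.to_datetime(day, unit="D").strftime("%Y-%m")
    out = []
    census = world.census
    for m in np.unique(month):
        sub = frame.loc[month == m]
        homes = infer_home_cbgs(sub, world)
        weights = persons_per_user(homes, census)
        if len(weights) == 0:
            continue
        weights = weights.copy()
        weights["winsorized"] = winsorize(weights["raw"].to_numpy(), lower, upper)
        weights["month"] = m
        weights = weights.reset_index().rename(columns={"index": "user_id"})
        out.append(weights[["month", "user_id", "home_cbg", "raw", "winsorized"]])
    if not out:
        return pd.DataFrame(columns=["month", "user_id", "home_cbg", "raw", "winsorized"])
    return pd.concat(out, ignore_index=True)
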