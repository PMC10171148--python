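"""Cleaning and partitioning of raw daily record drops.

Three steps, each conserving records exactly:

1. bounds filtering — impossible coordinates and points outside the study
   region are dropped;
2. date assignment — a record belongs to the local calendar date of its
   timestamp (fixed per-CBG UTC offsets, no daylight saving); it is kept
   only if it arrived in the daily file for that date or the next one,
   mirroring the vendor feed in which ~99.5% of records arrive within one
   day and the stragglers are discarded;
3. geographic partition — records are bucketed by (county, CBG) with a
   point-in-rectangle test; clustering later runs per bucket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import Rect
from .world import World

logger = logging.getLogger(__name__)


@dataclass
class IngestLog:
    """Record-conservation ledger: input = kept + all drop buckets."""

    n_input: int = 0
    n_invalid: int = 0  # unparseable / impossible coordinates
    n_oob: int = 0  # parseable but outside the study region
    n_late: int = 0  # arrived two or more days after the local date
    n_unassigned: int = 0  # inside the region but in no CBG rectangle
    n_kept: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_bounds(records: pd.DataFrame, region: Rect) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (kept, dropped) by a point-in-region test.

    Non-finite or physically impossible coordinates are dropped with a
    logged warning rather than raising.
    """
    lat = pd.to_numeric(records["lat"], errors="coerce").to_numpy(dtype=float)
    lon = pd.to_numeric(records["lon"], errors="coerce").to_numpy(dtype=float)
    invalid = ~np.isfinite(lat) | ~np.isfinite(lon) | (np.abs(lat) > 90.0) | (np.abs(lon) > 180.0)
    if invalid.any():
        logger.warning("dropping %d records with invalid coordinates", int(invalid.sum()))
    inside = np.zeros(len(records), dtype=bool)
    ok = ~invalid
    inside[ok] = region.contains(lat[ok], lon[ok])
    return records.loc[inside], records.loc[~inside]


def assign_dates(
    daily_files: Mapping[int, pd.DataFrame], world: World
) -> tuple[dict[int, pd.DataFrame], IngestLog]:
    """Assign records to their local calendar date with the one-day lag rule.

    A record with local date ``d`` is retained iff it arrived in the daily
    file for ``d`` or ``d + 1``; later (or earlier, which the feed never
    produces) arrivals are dropped and counted.  Records are first bounds-
    filtered against the world rectangle.  Output frames carry ``local_day``
    and the CBG index column ``cbg_ix``.
    """
    log = IngestLog()
    if not daily_files:
        return {}, log
    frames = [f for f in daily_files.values() if len(f)]
    if not frames:
        return {}, log
    allrec = pd.concat(frames, ignore_index=True)
    log.n_input = len(allrec)

    kept, dropped = filter_bounds(allrec, world.bounds)
    lat = pd.to_numeric(dropped["lat"], errors="coerce")
    lon = pd.to_numeric(dropped["lon"], errors="coerce")
    impossible = ~np.isfinite(lat) | ~np.isfinite(lon) | (lat.abs() > 90) | (lon.abs() > 180)
    log.n_invalid = int(impossible.sum())
    log.n_oob = len(dropped) - log.n_invalid

    kept = kept.copy()
    cbg_ix = world.cbg_index_of(kept["lat"].to_numpy(), kept["lon"].to_numpy())
    offsets = np.where(
        cbg_ix >= 0,
        world.cbg_offsets_min[np.clip(cbg_ix, 0, None)],
        world.default_utc_offset_min,
    )
    local_day = (kept["timestamp"].to_numpy() + offsets * 60) // 86400
    kept["cbg_ix"] = cbg_ix
    kept["local_day"] = local_day.astype(np.int64)

    lag = kept["arrival_day"].to_numpy() - local_day
    ok = (lag == 0) | (lag == 1)
    log.n_late = int((~ok).sum())
    kept = kept.loc[ok]
    log.n_kept = len(kept)

    out = {int(day): g.reset_index(drop=True) for day, g in kept.groupby("local_day", sort=True)}
    return out, log


@dataclass
class CleanRecordSet:
    """Bounds-filtered, date-assigned records for one local date, bucketed
    by (county id, CBG id)."""

    date: int  # local epoch-day
    partitions: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    n_retained: int = 0
    n_unassigned: int = 0

    def all_records(self) -> pd.DataFrame:
        if not self.partitions:
            return pd.DataFrame()
        return pd.concat(self.partitions.values(), ignore_index=True)


def partition(records: pd.DataFrame, world: World, date: int) -> CleanRecordSet:
    """Bucket one date's records by (county, CBG).

    Boundary points land in the lexicographically smallest CBG id (the
    containment test scans CBGs in id order).  Records in no CBG are
    dropped and counted.
    """
    out = CleanRecordSet(date=date)
    if len(records) == 0:
        return out
    if "cbg_ix" in records.columns:
        cbg_ix = records["cbg_ix"].to_numpy()
    else:
        cbg_ix = world.cbg_index_of(records["lat"].to_numpy(), records["lon"].to_numpy())
        records = records.assign(cbg_ix=cbg_ix)
    out.n_unassigned = int((cbg_ix < 0).sum())
    ids = world.cbg_ids
    counties = world.counties
    inside = records.loc[cbg_ix >= 0]
    for ix, g in inside.groupby("cbg_ix", sort=True):
        ix = int(ix)
        out.partitions[(counties[ix], ids[ix])] = g.reset_index(drop=True)
    out.n_retained = len(inside)
    return out


def ingest(
    daily_files: Mapping[int, pd.DataFrame], world: World
) -> tuple[dict[int, CleanRecordSet], IngestLog]:
    """Full ingestion: clean, date-assign and partition every daily drop."""
    by_date, log = assign_dates(daily_files, world)
    sets = {}
    for day, frame in by_date.items():
        cs = partition(frame, world, day)
        log.n_unassigned += cs.n_unassigned
        sets[day] = cs
    log.n_kept -= log.n_unassigned
    return sets, log


def clean_frame(
    daily_files: Mapping[int, pd.DataFrame], world: World
) -> tuple[pd.DataFrame, IngestLog]:
    """Vectorized ingestion for bulk runs: one frame with ``local_day`` and
    ``cbg_ix`` columns, records in no CBG dropped."""
    by_date, log = assign_dates(daily_files, world)
    if not by_date:
        return pd.DataFrame(), log
    frame = pd.concat(by_date.values(), ignore_index=True)
    unassigned = int((frame["cbg_ix"] < 0).sum())
    log.n_unassigned = unassigned
    log.n_kept -= unassigned
    return frame.loc[frame["cbg_ix"] >= 0].reset_index(drop=True), log
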