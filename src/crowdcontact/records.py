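"""LBS record schema, date arithmetic and daily-file CSV I/O.

A record is one observation of one anonymized user at one time point.  The
bulk pipeline keeps records in a :class:`pandas.DataFrame` (one row per
record); :class:`LbsRecord` is the scalar view used in small examples and
tests.  Daily files mirror the vendor's 24-hour drops: one headered CSV per
*arrival date*, which may trail the record's own local calendar date.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: columns present in the on-disk daily files
CSV_COLUMNS = ["user_id", "timestamp", "lat", "lon", "accuracy", "os"]

#: internal frame columns ("arrival_day" is carried by the file name on disk)
FRAME_COLUMNS = CSV_COLUMNS + ["arrival_day"]

_EPOCH = dt.date(1970, 1, 1)


def day_number(d: dt.date) -> int:
    """Days since the Unix epoch for a calendar date."""
    return (d - _EPOCH).days


def date_of(day: int) -> dt.date:
    return _EPOCH + dt.timedelta(days=int(day))


def weekday_of_day(day) -> np.ndarray:
    """Monday=0 .. Sunday=6 for epoch-day numbers (1970-01-01 was a Thursday)."""
    return (np.asarray(day, dtype=np.int64) + 3) % 7


@dataclass(frozen=True)
class LbsRecord:
    """One (user, time, position) observation."""

    user_id: str
    timestamp: int  # UTC seconds
    lat: float
    lon: float
    accuracy: float  # meters, > 0
    os: str
    arrival_day: int  # epoch-day of the daily file the record appeared in

    def __post_init__(self) -> None:
        if self.accuracy <= 0:
            raise ValueError("accuracy must be positive")


def records_to_frame(records: Iterable[LbsRecord]) -> pd.DataFrame:
    rows = [
        (r.user_id, r.timestamp, r.lat, r.lon, r.accuracy, r.os, r.arrival_day)
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=FRAME_COLUMNS)
    return _with_dtypes(frame)


def frame_to_records(frame: pd.DataFrame) -> list[LbsRecord]:
    return [
        LbsRecord(
            user_id=str(row.user_id),
            timestamp=int(row.timestamp),
            lat=float(row.lat),
            lon=float(row.lon),
            accuracy=float(row.accuracy),
            os=str(row.os),
            arrival_day=int(row.arrival_day),
        )
        for row in frame.itertuples(index=False)
    ]


def _with_dtypes(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["timestamp"] = frame["timestamp"].astype(np.int64)
    frame["lat"] = frame["lat"].astype(float)
    frame["lon"] = frame["lon"].astype(float)
    frame["accuracy"] = frame["accuracy"].astype(float)
    frame["arrival_day"] = frame["arrival_day"].astype(np.int64)
    return frame


def write_daily_files(frame: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write one ``YYYYMMDD.csv`` per arrival date; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for day, group in frame.groupby("arrival_day", sort=True):
        path = out / f"{date_of(int(day)):%Y%m%d}.csv"
        group[CSV_COLUMNS].to_csv(path, index=False)
        paths.append(path)
    return paths


def read_daily_files(in_dir: str | Path) -> dict[int, pd.DataFrame]:
    """Read ``YYYYMMDD.csv`` daily drops into an ``{arrival_day: frame}`` map."""
    files: dict[int, pd.DataFrame] = {}
    for path in sorted(Path(in_dir).glob("*.csv")):
        try:
            day = day_number(dt.datetime.strptime(path.stem, "%Y%m%d").date())
        except ValueError:
            continue
        frame = pd.read_csv(path, dtype={"user_id": str, "os": str})
        frame["arrival_day"] = np.int64(day)
        files[day] = _with_dtypes(frame)
    return files


def split_by_arrival(frame: pd.DataFrame) -> Mapping[int, pd.DataFrame]:
    """In-memory analogue of the daily drops."""
    return {int(day): g.reset_index(drop=True) for day, g in frame.groupby("arrival_day")}
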