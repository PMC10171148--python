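"""Person-minutes of social contact per cluster and the normalized index.

For a cluster with N estimated real persons (summed winsorized
persons-per-user over its unique users), bounding-box area A and contact
threshold C, the cluster area is tiled into N_C = ceil(A / (pi C^2))
contact circles (floored at one so a coincident-point cluster still forms
a single circle); each circle holds N_P = ceil(N / N_C) persons, each in
contact with the N_P - 1 others.  With T_u the average time a user spends
in the cluster, the person-minutes of contact are

    S = N * T_u * (N_P - 1),

and clusters with S <= 0 are dropped.  In the asymptotic regime of many
persons uniformly spread over a large area the ceilings vanish and
S -> N * T_u * (N pi C^2 / A - 1).

T_u is not measured per user (clusters are too fine-grained for dwell
times); it is inferred as records / (users * rate), where the rate is the
per-CBG, per-date records-per-user-per-minute, averaged over hours of the
day weighted by each hour's record count so that sparse sleeping hours do
not drag the estimate down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import Cluster, ClusterParams
from .world import World

#: SCI scale factor: the reference-date total maps to one million
DEFAULT_SCALE = 1_000_000.0


@dataclass(frozen=True)
class CbgRate:
    """Hour-weighted records per user per minute for one CBG and date."""

    cbg_id: str
    date: int
    rate_per_min: float
    hourly_counts: tuple = ()

    def __post_init__(self) -> None:
        if not self.rate_per_min > 0:
            raise ValueError("rate must be positive")


@dataclass
class ClusterMetrics:
    """Per-cluster contact arithmetic (one row of the metrics table)."""

    cluster_id: str
    n_persons: float  # N
    area_m2: float  # A
    duration_min: float  # T (reported; does not enter S)
    n_circles: int  # N_C
    avg_user_time_min: float  # T_u
    persons_per_circle: int  # N_P
    person_minutes: float  # S
    sci: float = float("nan")
    dropped: bool = False


def estimate_n(cluster_users, weights: pd.Series, fallback: float) -> float:
    """N: summed winsorized persons-per-user over the cluster's unique
    users; users without a weight (no weekend-night records that month)
    contribute the scope median ``fallback``."""
    total = 0.0
    for u in set(cluster_users):
        total += float(weights.get(u, fallback))
    return total


def bbox_area(x_min: float, x_max: float, y_min: float, y_max: float) -> float:
    """A: axis-aligned bounding-box area in m² (0 for coincident points)."""
    return max(x_max - x_min, 0.0) * max(y_max - y_min, 0.0)


def n_circles(area_m2: float, contact_threshold: float) -> int:
    """N_C = ceil(A / (pi C²)), floored at 1 for degenerate areas."""
    if area_m2 < 0:
        raise ValueError("area must be non-negative")
    if contact_threshold <= 0:
        raise ValueError("contact threshold must be positive")
    return max(1, math.ceil(area_m2 / (math.pi * contact_threshold**2)))


def cbg_rate(records: pd.DataFrame, utc_offset_min: int, *, cbg_id: str = "", date: int = 0) -> CbgRate:
    """Hour-weighted average records per user per minute for one CBG-date.

    Per hour h with records: r_h = records_h / users_h / 60; the returned
    rate is sum(w_h * r_h) / sum(w_h) with w_h = records_h.
    """
    if len(records) == 0:
        raise ValueError("cannot estimate a rate from zero records")
    local_sec = records["timestamp"].to_numpy() + utc_offset_min * 60
    hour = (local_sec % 86400) // 3600
    tab = pd.DataFrame({"hour": hour, "user_id": records["user_id"].to_numpy()})
    g = tab.groupby("hour", observed=True)["user_id"]
    counts = g.size()
    users = g.nunique()
    r_h = counts / users / 60.0
    rate = float((counts * r_h).sum() / counts.sum())
    return CbgRate(cbg_id=cbg_id, date=date, rate_per_min=rate,
                   hourly_counts=tuple(counts.items()))


def avg_user_time(n_records: int, n_users: int, rate_per_min: float) -> float:
    """T_u = records / (users * rate), minutes."""
    if rate_per_min <= 0:
        raise ValueError("rate must be positive")
    if n_users <= 0:
        raise ValueError("cluster must contain at least one user")
    return n_records / (n_users * rate_per_min)


def contacts(n_persons: float, avg_time_min: float, num_circles: int) -> tuple[int, float, bool]:
    """(N_P, S, dropped): persons per circle, person-minutes, drop flag."""
    if num_circles < 1:
        raise ValueError("need at least one circle")
    n_p = max(1, math.ceil(n_persons / num_circles))
    s = n_persons * avg_time_min * (n_p - 1)
    return n_p, s, not (s > 0.0)


def normalize(person_minutes, reference_total: float, scale: float = DEFAULT_SCALE):
    """SCI = scale * S / reference_total."""
    if not reference_total > 0:
        raise ValueError("reference total must be positive")
    return np.asarray(person_minutes, dtype=float) * (scale / reference_total)


def cluster_metrics(
    cluster: Cluster,
    weights: pd.Series,
    rate: CbgRate,
    params: ClusterParams,
    *,
    weight_fallback: float | None = None,
) -> ClusterMetrics:
    """Full Algorithm-2 arithmetic for one :class:`Cluster` object."""
    fallback = (
        weight_fallback
        if weight_fallback is not None
        else float(np.median(weights.to_numpy())) if len(weights) else 0.0
    )
    n = estimate_n(cluster.user_ids, weights, fallback)
    area = bbox_area(cluster.x_min, cluster.x_max, cluster.y_min, cluster.y_max)
    nc = n_circles(area, params.contact_threshold)
    t_u = avg_user_time(cluster.n_records, cluster.n_users, rate.rate_per_min)
    n_p, s, dropped = contacts(n, t_u, nc)
    return ClusterMetrics(
        cluster_id=f"{cluster.date}-{cluster.cbg_id}-{cluster.id}",
        n_persons=n,
        area_m2=area,
        duration_min=cluster.duration,
        n_circles=nc,
        avg_user_time_min=t_u,
        persons_per_circle=n_p,
        person_minutes=s,
        dropped=dropped,
    )


def metrics_frame(
    stats: pd.DataFrame,
    contact_threshold: float,
) -> pd.DataFrame:
    """Vectorized Algorithm-2 arithmetic over a per-cluster stats frame.

    ``stats`` needs columns n_records, n_users, n_persons, area, duration,
    rate.  Adds n_circles, t_u, n_p, s and the dropped flag.
    """
    out = stats.copy()
    area = out["area"].to_numpy(dtype=float)
    nc = np.maximum(
        1, np.ceil(area / (math.pi * contact_threshold**2)).astype(np.int64)
    )
    t_u = out["n_records"].to_numpy() / (
        out["n_users"].to_numpy() * out["rate"].to_numpy()
    )
    n = out["n_persons"].to_numpy(dtype=float)
    n_p = np.maximum(1, np.ceil(n / nc).astype(np.int64))
    s = n * t_u * (n_p - 1)
    out["n_circles"] = nc
    out["t_u"] = t_u
    out["n_p"] = n_p
    out["s"] = s
    out["dropped"] = ~(s > 0.0)
    return out


def cbg_rates_frame(frame: pd.DataFrame, world: World) -> pd.DataFrame:
    """Hour-weighted rates for every (local_day, cbg_ix) in a cleaned frame.

    Returns columns local_day, cbg_ix, rate.  Uses the same hour-weighted
    average as :func:`cbg_rate`, vectorized across partitions.
    """
    offsets = world.cbg_offsets_min[frame["cbg_ix"].to_numpy()]
    local_sec = frame["timestamp"].to_numpy() + offsets * 60
    hour = ((local_sec % 86400) // 3600).astype(np.int64)
    tab = pd.DataFrame(
        {
            "local_day": frame["local_day"].to_numpy(),
            "cbg_ix": frame["cbg_ix"].to_numpy(),
            "hour": hour,
            "user_ix": frame["user_ix"].to_numpy()
            if "user_ix" in frame.columns
            else frame["user_id"].to_numpy(),
        }
    )
    g = tab.groupby(["local_day", "cbg_ix", "hour"], observed=True)["user_ix"]
    counts = g.size().rename("n")
    users = g.nunique().rename("u")
    hourly = pd.concat([counts, users], axis=1).reset_index()
    hourly["r_h"] = hourly["n"] / hourly["u"] / 60.0
    hourly["wr"] = hourly["n"] * hourly["r_h"]
    agg = hourly.groupby(["local_day", "cbg_ix"], observed=True)[["wr", "n"]].sum()
    agg["rate"] = agg["wr"] / agg["n"]
    return agg.reset_index()[["local_day", "cbg_ix", "rate"]]
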