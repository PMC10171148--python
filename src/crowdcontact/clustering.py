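"""Spatiotemporal DBSCAN over (x, y, t) point records.

Points are records projected to planar meters with time in minutes.  The
ε-neighborhood is the *conjunction* of a spatial disc and a time window:
q is a neighbor of p iff planar_dist(p, q) <= eps_space AND
|t_p - t_q| <= eps_time, both boundaries inclusive.  A point is a core
point iff at least ``min_points`` OTHER points lie in its neighborhood
(self excluded — note the common DBSCAN convention counts self, this one
does not).  Clusters are connected components of the core-point neighbor
graph; each non-core point joins the cluster of its nearest core neighbor
(nearness in the scaled max-norm, ties to the smallest cluster id) or is
noise.

Two independent implementations are provided: a sorted-sweep union-find
version compiled with numba for bulk runs, and an O(n²) matrix oracle
(:func:`dbscan_oracle_labels`) used to cross-check it in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import project

NOISE = -1


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN thresholds plus the downstream contact threshold.

    ``metric="conjunction"`` is the AND of the spatial and temporal
    thresholds (the default); ``"scaled_euclidean"`` uses the ellipsoidal
    ball (d_space/eps_space)² + (dt/eps_time)² <= 1 instead, for
    sensitivity work.
    """

    eps_space: float = 15.0  # meters
    eps_time: float = 20.0  # minutes
    min_points: int = 10  # M: other records required in the neighborhood
    contact_threshold: float = 15.0  # C, meters; consumed by the contact index
    metric: str = "conjunction"

    def __post_init__(self) -> None:
        if self.eps_space <= 0 or self.eps_time <= 0:
            raise ValueError("eps thresholds must be positive")
        if self.min_points <= 0:
            raise ValueError("min_points must be positive")
        if self.contact_threshold <= 0:
            raise ValueError("contact threshold must be positive")
        if self.metric not in ("conjunction", "scaled_euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass(frozen=True)
class ClusterPoint:
    """A projected record: planar meters and minutes from partition epoch."""

    x: float
    y: float
    t: float
    record: object | None = None


@dataclass
class Cluster:
    """A connected spatiotemporal crowd."""

    id: int
    indices: np.ndarray  # positions into the partition's point arrays
    n_records: int
    user_ids: tuple
    x_min: float
    x_max: float
    y_min: float
    y_max: float
    t_min: float
    t_max: float
    cbg_id: str | None = None
    date: int | None = None
    origin: tuple[float, float] | None = None  # (lat0, lon0) of the projection

    @property
    def n_users(self) -> int:
        return len(self.user_ids)

    @property
    def duration(self) -> float:
        return self.t_max - self.t_min

    @property
    def bbox_area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


def project_records(records: pd.DataFrame, origin: tuple[float, float]):
    """Project one partition's records about ``origin`` = (lat0, lon0).

    Returns (x meters, y meters, t minutes from the origin local midnight
    implied by the records' own ``local_day``/offset — here simply minutes
    from the earliest possible epoch, since only differences matter).
    """
    x, y = project(records["lat"].to_numpy(), records["lon"].to_numpy(), origin[0], origin[1])
    t = records["timestamp"].to_numpy(dtype=float) / 60.0
    return x, y, t


def is_neighbor(p: ClusterPoint, q: ClusterPoint, params: ClusterParams) -> bool:
    """Scalar ε-neighborhood test (boundary inclusive)."""
    dx = p.x - q.x
    dy = p.y - q.y
    dt = p.t - q.t
    if params.metric == "conjunction":
        return dx * dx + dy * dy <= params.eps_space**2 and abs(dt) <= params.eps_time
    return (dx * dx + dy * dy) / params.eps_space**2 + (dt * dt) / params.eps_time**2 <= 1.0


# ---------------------------------------------------------------------------
# fast implementation: time-sorted sweep + union-find (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _count_neighbors(x, y, t, es2, et, scaled):
    n = x.shape[0]
    counts = np.zeros(n, dtype=np.int64)
    lo = 0
    for i in range(n):
        while t[i] - t[lo] > et:
            lo += 1
        for j in range(lo, n):
            if t[j] - t[i] > et:
                break
            if j == i:
                continue
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            d2 = dx * dx + dy * dy
            if scaled:
                dt = t[i] - t[j]
                if d2 / es2 + (dt * dt) / (et * et) <= 1.0:
                    counts[i] += 1
            else:
                if d2 <= es2:
                    counts[i] += 1
    return counts


@njit(cache=True)
def _find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True)
def _union_cores(x, y, t, core, es2, et, scaled):
    n = x.shape[0]
    parent = np.arange(n)
    lo = 0
    for i in range(n):
        while t[i] - t[lo] > et:
            lo += 1
        if not core[i]:
            continue
        for j in range(i + 1, n):
            if t[j] - t[i] > et:
                break
            if not core[j]:
                continue
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            d2 = dx * dx + dy * dy
            ok = False
            if scaled:
                dt = t[i] - t[j]
                ok = d2 / es2 + (dt * dt) / (et * et) <= 1.0
            else:
                ok = d2 <= es2
            if ok:
                ri = _find(parent, i)
                rj = _find(parent, j)
                if ri != rj:
                    if ri < rj:
                        parent[rj] = ri
                    else:
                        parent[ri] = rj
    for i in range(n):
        parent[i] = _find(parent, i)
    return parent


@njit(cache=True)
def _assign_borders(x, y, t, core, labels, es2, et, scaled):
    n = x.shape[0]
    out = labels.copy()
    lo = 0
    for i in range(n):
        while t[i] - t[lo] > et:
            lo += 1
        if core[i]:
            continue
        best_key = 1.0e300
        best_label = -1
        for j in range(lo, n):
            if t[j] - t[i] > et:
                break
            if not core[j] or j == i:
                continue
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            d2 = dx * dx + dy * dy
            dt = t[i] - t[j]
            if scaled:
                key = d2 / es2 + (dt * dt) / (et * et)
                if key > 1.0:
                    continue
            else:
                if d2 > es2:
                    continue
                key = d2 / es2
                k2 = (dt * dt) / (et * et)
                if k2 > key:
                    key = k2
            if key < best_key or (key == best_key and labels[j] < best_label):
                best_key = key
                best_label = labels[j]
        out[i] = best_label
    return out


def _canonical_core_labels(components: np.ndarray, core: np.ndarray, order_rank: np.ndarray) -> np.ndarray:
    """Relabel core components 0..k-1 by their minimal member under the
    canonical (t, x, y, position) ordering; non-cores get -1."""
    labels = np.full(components.shape[0], NOISE, dtype=np.int64)
    core_ix = np.flatnonzero(core)
    if core_ix.size == 0:
        return labels
    _, comp = np.unique(components[core_ix], return_inverse=True)
    n_comp = int(comp.max()) + 1
    best = np.full(n_comp, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(best, comp, order_rank[core_ix])
    remap = np.empty(n_comp, dtype=np.int64)
    remap[np.argsort(best, kind="stable")] = np.arange(n_comp)
    labels[core_ix] = remap[comp]
    return labels


def _order_rank(x: np.ndarray, y: np.ndarray, t: np.ndarray) -> np.ndarray:
    order = np.lexsort((np.arange(x.shape[0]), y, x, t))
    rank = np.empty(x.shape[0], dtype=np.int64)
    rank[order] = np.arange(x.shape[0])
    return rank


def dbscan_labels(x, y, t, params: ClusterParams) -> np.ndarray:
    """Cluster labels for each point (noise = -1); fast implementation."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    t = np.ascontiguousarray(t, dtype=np.float64)
    n = x.shape[0]
    if n == 0:
        return np.empty(0, dtype=np.int64)
    order = np.argsort(t, kind="stable")
    xs, ys, ts = x[order], y[order], t[order]
    es2 = params.eps_space * params.eps_space
    et = float(params.eps_time)
    scaled = params.metric == "scaled_euclidean"

    counts = _count_neighbors(xs, ys, ts, es2, et, scaled)
    core = counts >= params.min_points
    parent = _union_cores(xs, ys, ts, core, es2, et, scaled)
    labels_sorted = _canonical_core_labels(parent, core, _order_rank(xs, ys, ts))
    labels_sorted = _assign_borders(xs, ys, ts, core, labels_sorted, es2, et, scaled)

    labels = np.empty(n, dtype=np.int64)
    labels[order] = labels_sorted
    return labels


# ---------------------------------------------------------------------------
# oracle: exhaustive pairwise matrices + scipy connected components
# ---------------------------------------------------------------------------

ORACLE_MAX_POINTS = 5000


def dbscan_oracle_labels(x, y, t, params: ClusterParams) -> np.ndarray:
    """O(n²) reference implementation; refuses n > 5000."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    n = x.shape[0]
    if n > ORACLE_MAX_POINTS:
        raise ValueError(f"oracle limited to {ORACLE_MAX_POINTS} points, got {n}")
    if n == 0:
        return np.empty(0, dtype=np.int64)

    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    dt = t[:, None] - t[None, :]
    d2 = dx * dx + dy * dy
    es2 = params.eps_space * params.eps_space
    et2 = params.eps_time * params.eps_time
    if params.metric == "scaled_euclidean":
        key = d2 / es2 + (dt * dt) / et2
        neighbor = key <= 1.0
    else:
        key = np.maximum(d2 / es2, (dt * dt) / et2)
        neighbor = (d2 <= es2) & (np.abs(dt) <= params.eps_time)
    np.fill_diagonal(neighbor, False)

    core = neighbor.sum(axis=1) >= params.min_points
    adj = neighbor & core[:, None] & core[None, :]
    graph = coo_matrix(adj)
    _, comp = connected_components(graph, directed=False)

    labels = _canonical_core_labels(comp, core, _order_rank(x, y, t))

    for i in np.flatnonzero(~core):
        cand = np.flatnonzero(neighbor[i] & core)
        if cand.size == 0:
            continue
        keys = key[i, cand]
        best = keys.min()
        tied = cand[keys == best]
        labels[i] = labels[tied].min()
    return labels


# ---------------------------------------------------------------------------
# cluster objects
# ---------------------------------------------------------------------------


def clusters_from_labels(
    labels: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    t: np.ndarray,
    user_ids: Sequence | None = None,
    *,
    cbg_id: str | None = None,
    date: int | None = None,
    origin: tuple[float, float] | None = None,
) -> list[Cluster]:
    clusters = []
    for lab in np.unique(labels[labels >= 0]):
        ix = np.flatnonzero(labels == lab)
        users = (
            tuple(sorted(set(np.asarray(user_ids, dtype=object)[ix])))
            if user_ids is not None
            else ()
        )
        clusters.append(
            Cluster(
                id=int(lab),
                indices=ix,
                n_records=int(ix.size),
                user_ids=users,
                x_min=float(x[ix].min()),
                x_max=float(x[ix].max()),
                y_min=float(y[ix].min()),
                y_max=float(y[ix].max()),
                t_min=float(t[ix].min()),
                t_max=float(t[ix].max()),
                cbg_id=cbg_id,
                date=date,
                origin=origin,
            )
        )
    return clusters


def dbscan(
    points: pd.DataFrame,
    params: ClusterParams,
    *,
    cbg_id: str | None = None,
    date: int | None = None,
    origin: tuple[float, float] | None = None,
) -> list[Cluster]:
    """Cluster a partition given as a frame with x, y, t (and optionally
    ``user_id``) columns; returns :class:`Cluster` objects."""
    if len(points) == 0:
        return []
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    t = points["t"].to_numpy(dtype=float)
    labels = dbscan_labels(x, y, t, params)
    users = points["user_id"].to_numpy() if "user_id" in points.columns else None
    return clusters_from_labels(
        labels, x, y, t, users, cbg_id=cbg_id, date=date, origin=origin
    )


def dbscan_oracle(
    points: pd.DataFrame,
    params: ClusterParams,
    *,
    cbg_id: str | None = None,
    date: int | None = None,
    origin: tuple[float, float] | None = None,
) -> list[Cluster]:
    if len(points) == 0:
        return []
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    t = points["t"].to_numpy(dtype=float)
    labels = dbscan_oracle_labels(x, y, t, params)
    users = points["user_id"].to_numpy() if "user_id" in points.columns else None
    return clusters_from_labels(
        labels, x, y, t, users, cbg_id=cbg_id, date=date, origin=origin
    )


def partition_labels(x, y, t, params) -> np.ndarray:  # pragma: no cover - alias
    return dbscan_labels(x, y, t, params)
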