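"""POI attribution, ZCTA-level rollup, size-distribution fits and the
published CSV formats.

A cluster contributes to a POI the fraction of its bounding-box area that
falls inside the POI's disc (exact circle-rectangle intersection, no
sampling).  Contributions of all clusters to same-type POIs within a ZCTA
are summed into one daily record per (ZCTA, POI type).  sqrt(overlap area)
is the characteristic cluster size whose distribution per POI type is
summarized and, optionally, fitted against several candidate families.

The output schema reproduces the published format verbatim, including the
historical field spelling ``Avergage_Time``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import circle_rect_overlap_area, project
from .records import date_of
from .world import POI, World

logger = logging.getLogger(__name__)

OUTPUT_COLUMNS = [
    "ZCTA5",
    "POI_Type",
    "Number_of_Clusters",
    "Cluster_Size_Mean",
    "Cluster_Size_Variance",
    "Avergage_Time",  # sic: published spelling
    "SCI",
]

POI_FILE_COLUMNS = ["POI_Type", "POI_Subtype", "Radius"]

#: candidate families for the cluster-size distribution
SIZE_FIT_FAMILIES: dict[str, stats.rv_continuous] = {
    "f": stats.f,
    "chi2": stats.chi2,
    "weibull": stats.weibull_min,
    "lognorm": stats.lognorm,
    "gamma": stats.gamma,
    "powerlognorm": stats.powerlognorm,
}


@dataclass(frozen=True)
class Overlap:
    cluster_id: str
    poi_id: str
    fraction: float
    area_m2: float


def overlap_fraction(
    bbox: tuple[float, float, float, float],
    poi_center_xy: tuple[float, float],
    radius_m: float,
) -> tuple[float, float]:
    """(fraction, overlap area m²) of a cluster bbox inside a POI disc.

    ``bbox`` is (x_min, x_max, y_min, y_max) in the same projected frame as
    the POI center.  A zero-area bbox counts as fully inside iff its
    midpoint lies in the disc (its overlap area is then 0).
    """
    x0, x1, y0, y1 = bbox
    cx, cy = poi_center_xy
    box_area = max(x1 - x0, 0.0) * max(y1 - y0, 0.0)
    if box_area <= 0.0:
        mx, my = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
        inside = (mx - cx) ** 2 + (my - cy) ** 2 <= radius_m**2
        return (1.0 if inside else 0.0), 0.0
    area = circle_rect_overlap_area(cx, cy, radius_m, x0, y0, x1, y1)
    frac = min(max(area / box_area, 0.0), 1.0)
    return frac, area


def cluster_poi_overlaps(metrics: pd.DataFrame, world: World) -> pd.DataFrame:
    """Overlap rows (cluster_id, poi_id, fraction, overlap_area) with fraction > 0.

    ``metrics`` must carry cluster_id, cbg_ix, and the projected bbox
    columns x_min..y_max together with origin_lat/origin_lon.  POI centers
    are projected into each cluster's own frame.
    """
    rows = []
    if len(metrics) == 0:
        return pd.DataFrame(columns=["cluster_id", "poi_id", "fraction", "overlap_area"])
    pois = world.pois
    plat = np.array([p.lat for p in pois])
    plon = np.array([p.lon for p in pois])
    prad = np.array([p.radius_m for p in pois])
    pids = np.array([p.id for p in pois], dtype=object)
    for origin, group in metrics.groupby(["origin_lat", "origin_lon"], sort=False):
        px, py = project(plat, plon, origin[0], origin[1])
        for row in group.itertuples(index=False):
            half_dx = 0.5 * (row.x_max - row.x_min)
            half_dy = 0.5 * (row.y_max - row.y_min)
            mx = 0.5 * (row.x_min + row.x_max)
            my = 0.5 * (row.y_min + row.y_max)
            reach = np.hypot(half_dx, half_dy) + prad
            near = np.hypot(px - mx, py - my) <= reach + 1e-9
            for j in np.flatnonzero(near):
                frac, area = overlap_fraction(
                    (row.x_min, row.x_max, row.y_min, row.y_max),
                    (px[j], py[j]),
                    prad[j],
                )
                if frac > 0.0:
                    rows.append((row.cluster_id, pids[j], frac, area))
    return pd.DataFrame(rows, columns=["cluster_id", "poi_id", "fraction", "overlap_area"])


def aggregate(
    metrics: pd.DataFrame,
    overlaps: pd.DataFrame,
    world: World,
    *,
    sample_variance: bool = True,
) -> pd.DataFrame:
    """Daily (ZCTA, POI type) records from per-cluster metrics.

    Per (date, ZCTA, POI_Type): SCI is the overlap-fraction-weighted sum of
    cluster SCI; sizes are sqrt(overlap area) per contributing
    cluster-POI pair; Avergage_Time is the unweighted mean T_u over
    contributing clusters; Number_of_Clusters counts distinct clusters.
    """
    cols = ["date", "ZCTA5", "POI_Type", "Number_of_Clusters", "Cluster_Size_Mean",
            "Cluster_Size_Variance", "Avergage_Time", "SCI"]
    if len(metrics) == 0 or len(overlaps) == 0:
        return pd.DataFrame(columns=cols)
    poi_info = pd.DataFrame(
        [(p.id, p.type, p.zcta) for p in world.pois],
        columns=["poi_id", "POI_Type", "ZCTA5"],
    )
    kept = metrics.loc[~metrics["dropped"].astype(bool)]
    tab = overlaps.merge(kept, on="cluster_id", how="inner").merge(poi_info, on="poi_id")
    if len(tab) == 0:
        return pd.DataFrame(columns=cols)
    tab["weighted_sci"] = tab["fraction"] * tab["sci"]
    tab["size"] = np.sqrt(np.maximum(tab["overlap_area"], 0.0))
    ddof = 1 if sample_variance else 0

    def _one(g: pd.DataFrame) -> pd.Series:
        distinct = g.drop_duplicates("cluster_id")
        sizes = g["size"].to_numpy()
        var = float(np.var(sizes, ddof=ddof)) if len(sizes) > ddof else 0.0
        return pd.Series(
            {
                "Number_of_Clusters": int(distinct["cluster_id"].nunique()),
                "Cluster_Size_Mean": float(sizes.mean()),
                "Cluster_Size_Variance": var,
                "Avergage_Time": float(distinct["t_u"].mean()),
                "SCI": float(g["weighted_sci"].sum()),
            }
        )

    out = (
        tab.groupby(["date", "ZCTA5", "POI_Type"], observed=True)
        .apply(_one, include_groups=False)
        .reset_index()
    )
    out["Number_of_Clusters"] = out["Number_of_Clusters"].astype(int)
    return out[cols]


def fit_cluster_sizes(
    sizes, *, families: Sequence[str] | None = None, min_sizes: int = 50
) -> pd.DataFrame:
    """Maximum-likelihood fits of candidate families to cluster sizes.

    Non-positive sizes are excluded (and logged); a constant sample is
    refused.  Returns one row per family with the fitted shape parameters
    and the Kolmogorov-Smirnov statistic, ranked best first.
    """
    v = np.asarray(sizes, dtype=float)
    n_bad = int((~(v > 0)).sum())
    if n_bad:
        logger.info("excluding %d non-positive sizes from the fit", n_bad)
    v = v[v > 0]
    if v.size < min_sizes:
        raise ValueError(f"need at least {min_sizes} positive sizes, got {v.size}")
    if np.ptp(v) == 0.0:
        raise ValueError("degenerate (constant) size sample: nothing to fit")
    names = list(families) if families is not None else list(SIZE_FIT_FAMILIES)
    rows = []
    for name in names:
        dist = SIZE_FIT_FAMILIES[name]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                params = dist.fit(v, floc=0.0)
                ks = stats.kstest(v, dist.cdf, args=params).statistic
            except Exception:  # fit failure: rank last
                params, ks = (), float("inf")
        rows.append((name, params, float(ks)))
    out = pd.DataFrame(rows, columns=["family", "params", "ks_statistic"])
    out = out.sort_values("ks_statistic", kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def write_outputs(
    records: pd.DataFrame,
    pois: Sequence[POI],
    out_dir: str | Path,
    *,
    region: str,
    overwrite: bool = False,
) -> list[Path]:
    """Write the published file tree: ``<region>/<YYYYMMDD>`` daily CSVs
    plus one ``POI.csv`` catalogue."""
    out = Path(out_dir)
    region_dir = out / region
    region_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for day, group in records.groupby("date", sort=True):
        path = region_dir / f"{date_of(int(day)):%Y%m%d}"
        if path.exists() and not overwrite:
            raise FileExistsError(f"refusing to overwrite {path}")
        group[OUTPUT_COLUMNS].to_csv(path, index=False)
        paths.append(path)
    poi_path = out / "POI.csv"
    if poi_path.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite {poi_path}")
    cat = pd.DataFrame(
        sorted({(p.type, p.subtype, p.radius_m) for p in pois}),
        columns=POI_FILE_COLUMNS,
    )
    cat["Radius"] = cat["Radius"].map(lambda r: int(r) if float(r).is_integer() else r)
    cat.to_csv(poi_path, index=False)
    paths.append(poi_path)
    return paths


def read_outputs(out_dir: str | Path, region: str) -> pd.DataFrame:
    """Round-trip reader for the published daily files."""
    frames = []
    import datetime as dt

    from .records import day_number

    for path in sorted((Path(out_dir) / region).iterdir()):
        try:
            day = day_number(dt.datetime.strptime(path.name, "%Y%m%d").date())
        except ValueError:
            continue
        frame = pd.read_csv(path, dtype={"ZCTA5": str})
        frame.insert(0, "date", day)
        frames.append(frame)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
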