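"""End-to-end pipeline: simulate -> ingest -> cluster -> weigh -> index ->
aggregate, plus the daily-trend series and the parameter-sensitivity grid.

The pipeline is deterministic for a fixed config seed; a JSON-able run
manifest captures every parameter, derived seed and drop count so a run
can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__ as _pkg_version
from .aggregation import aggregate, cluster_poi_overlaps, write_outputs
from .clustering import ClusterParams, dbscan_labels
from .contact_index import DEFAULT_SCALE, cbg_rates_frame, metrics_frame, normalize
from .ingestion import IngestLog, clean_frame
from .records import date_of, day_number, split_by_arrival
from .simulate import (
    GatheringConfig,
    GatheringPlan,
    generate_records,
    inject_defects,
    plan_gatherings,
)
from .weighting import monthly_weights
from .world import World, WorldConfig, generate_world

#: the sensitivity grid of (eps_space m, contact threshold C m) pairs,
#: evaluated against the (15, 15) baseline
SENSITIVITY_GRID: tuple[tuple[float, float], ...] = (
    (10.0, 5.0),
    (15.0, 10.0),
    (15.0, 20.0),
    (20.0, 25.0),
    (25.0, 30.0),
)
BASELINE_PARAMS: tuple[float, float] = (15.0, 15.0)


@dataclass(frozen=True)
class SimulationConfig:
    days: int = 30
    start_date: str = "2020-01-01"
    cadence_per_day: float = 120.0
    night_multiplier: float = 0.5
    late_fraction: float = 0.005
    late_tail: float = 0.0
    oob_fraction: float = 0.001
    gatherings: GatheringConfig = field(default_factory=GatheringConfig)
    gatherings_per_day: int | None = None  # pin the plan count (recovery studies)
    daily_activity: float | None = None  # None: default churn profile; 1.0: full panel

    @property
    def start_day(self) -> int:
        return day_number(dt.date.fromisoformat(self.start_date))


@dataclass(frozen=True)
class PipelineConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    params: ClusterParams = field(default_factory=ClusterParams)
    lower_percentile: float = 5.0
    upper_percentile: float = 95.0
    reference_date: str | None = None  # default: the run's first date
    scale: float = DEFAULT_SCALE
    seed: int = 0

    @property
    def reference_day(self) -> int:
        if self.reference_date is not None:
            return day_number(dt.date.fromisoformat(self.reference_date))
        return self.simulation.start_day

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "world" in kwargs:
            w = dict(kwargs["world"])
            if "poi_types" in w:
                from .world import PoiType

                w["poi_types"] = tuple(
                    PoiType(**p) if isinstance(p, dict) else PoiType(*p)
                    for p in w["poi_types"]
                )
            for key in ("population_range", "os_labels", "os_probs"):
                if key in w and isinstance(w[key], list):
                    w[key] = tuple(w[key])
            kwargs["world"] = WorldConfig(**w)
        if "simulation" in kwargs:
            s = dict(kwargs["simulation"])
            if "gatherings" in s:
                g = dict(s["gatherings"])
                for k in ("participants", "duration_min", "spread_m", "start_hour"):
                    if k in g:
                        g[k] = tuple(g[k])
                s["gatherings"] = GatheringConfig(**g)
            kwargs["simulation"] = SimulationConfig(**s)
        if "params" in kwargs:
            kwargs["params"] = ClusterParams(**kwargs["params"])
        return cls(**kwargs)

    def manifest(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "package_version": _pkg_version,
            "config": enc(self),
        }


@dataclass
class RunResult:
    config: PipelineConfig
    world: World
    records: pd.DataFrame  # raw simulated stream (with defects)
    clean: pd.DataFrame  # ingested records with cbg_ix / local_day
    ingest_log: IngestLog
    weights: pd.DataFrame  # monthly persons-per-user
    metrics: pd.DataFrame  # per-cluster Algorithm-2 table
    poi_day: pd.DataFrame  # (date, ZCTA, POI type) records
    daily: pd.Series  # normalized daily total contact series
    plans: list[GatheringPlan] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path, *, overwrite: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_outputs(
            self.poi_day, self.world.pois, out, region=self.world.region_name,
            overwrite=overwrite,
        )
        self.metrics.to_csv(out / "cluster_metrics.csv", index=False)
        self.weights.to_csv(out / "weights.csv", index=False)
        self.daily.rename("normalized_total").to_csv(out / "daily_totals.csv")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str))


def _derive_seeds(seed: int, n: int = 4) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def simulate_stream(
    config: PipelineConfig,
) -> tuple[World, list[GatheringPlan], pd.DataFrame]:
    """World, gathering truth and defect-injected record stream."""
    s_world, s_plans, s_records, s_defects = _derive_seeds(config.seed)
    world = generate_world(config.world, s_world)
    sim = config.simulation
    plans = plan_gatherings(
        world,
        start_day=sim.start_day,
        days=sim.days,
        seed=s_plans,
        config=sim.gatherings,
        exact_per_day=sim.gatherings_per_day,
    )
    records = generate_records(
        world,
        plans,
        sim.days,
        start_day=sim.start_day,
        cadence_per_day=sim.cadence_per_day,
        seed=s_records,
        night_multiplier=sim.night_multiplier,
        daily_activity=sim.daily_activity,
    )
    injected = inject_defects(
        records,
        sim.late_fraction,
        sim.oob_fraction,
        s_defects,
        late_tail=sim.late_tail,
        world=world,
    )
    return world, plans, injected.records


def cluster_stats(
    clean: pd.DataFrame,
    world: World,
    weights: pd.DataFrame,
    params: ClusterParams,
) -> pd.DataFrame:
    """Per-cluster statistics for every (date, CBG) partition.

    Returns one row per cluster with the columns consumed by
    :func:`crowdcontact.contact_index.metrics_frame` plus geometry columns
    for POI attribution.  Pure function of the cleaned records and eps
    parameters (the contact threshold does not enter).
    """
    from .geometry import project

    if len(clean) == 0:
        return pd.DataFrame()
    rates = cbg_rates_frame(clean, world).set_index(["local_day", "cbg_ix"])["rate"]

    n_users_total = len(world.users)
    month_weights: dict[str, np.ndarray] = {}
    uid_pos = {u.id: i for i, u in enumerate(world.users)}
    for m, g in weights.groupby("month"):
        arr = np.full(n_users_total, float(np.median(g["winsorized"])))
        ix = np.array([uid_pos[u] for u in g["user_id"]], dtype=np.int64)
        arr[ix] = g["winsorized"].to_numpy()
        month_weights[m] = arr

    cbg_ids = world.cbg_ids
    arrays = world._arrays()
    rows = []
    for (day, cbg_ix), part in clean.groupby(["local_day", "cbg_ix"], sort=True):
        day, cbg_ix = int(day), int(cbg_ix)
        lat0 = 0.5 * (arrays["lat_min"][cbg_ix] + arrays["lat_max"][cbg_ix])
        lon0 = 0.5 * (arrays["lon_min"][cbg_ix] + arrays["lon_max"][cbg_ix])
        x, y = project(part["lat"].to_numpy(), part["lon"].to_numpy(), lat0, lon0)
        t = part["timestamp"].to_numpy(dtype=float) / 60.0
        labels = dbscan_labels(x, y, t, params)
        mask = labels >= 0
        if not mask.any():
            continue
        month = f"{date_of(day):%Y-%m}"
        warr = month_weights.get(month)
        if warr is None:
            warr = np.full(n_users_total, 1.0)
        sub = pd.DataFrame(
            {
                "label": labels[mask],
                "x": x[mask],
                "y": y[mask],
                "t": t[mask],
                "user_ix": part["user_ix"].to_numpy()[mask],
            }
        )
        g = sub.groupby("label", sort=True)
        agg = g.agg(
            n_records=("label", "size"),
            x_min=("x", "min"),
            x_max=("x", "max"),
            y_min=("y", "min"),
            y_max=("y", "max"),
            t_min=("t", "min"),
            t_max=("t", "max"),
        )
        users = sub.drop_duplicates(["label", "user_ix"])
        agg["n_users"] = users.groupby("label").size()
        agg["n_persons"] = users.groupby("label")["user_ix"].agg(
            lambda ix: warr[ix.to_numpy()].sum()
        )
        agg = agg.reset_index()
        rate = float(rates.loc[(day, cbg_ix)])
        for r in agg.itertuples(index=False):
            rows.append(
                (
                    f"{day}-{cbg_ids[cbg_ix]}-{r.label}",
                    day,
                    cbg_ix,
                    cbg_ids[cbg_ix],
                    int(r.n_records),
                    int(r.n_users),
                    float(r.n_persons),
                    (r.x_max - r.x_min) * (r.y_max - r.y_min),
                    r.t_max - r.t_min,
                    rate,
                    r.x_min,
                    r.x_max,
                    r.y_min,
                    r.y_max,
                    r.t_min,
                    r.t_max,
                    float(lat0),
                    float(lon0),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "date", "cbg_ix", "cbg_id", "n_records", "n_users",
            "n_persons", "area", "duration", "rate", "x_min", "x_max", "y_min",
            "y_max", "t_min", "t_max", "origin_lat", "origin_lon",
        ],
    )


def finalize_metrics(
    stats: pd.DataFrame,
    contact_threshold: float,
    reference_day: int,
    scale: float = DEFAULT_SCALE,
) -> pd.DataFrame:
    """Apply the contact arithmetic and normalize to the SCI."""
    if len(stats) == 0:
        raise ValueError("no clusters to normalize")
    m = metrics_frame(stats, contact_threshold)
    kept = ~m["dropped"]
    ref = float(m.loc[kept & (m["date"] == reference_day), "s"].sum())
    if not ref > 0:
        raise ValueError(f"reference date {reference_day} has no positive contact total")
    m["sci"] = 0.0
    m.loc[kept, "sci"] = normalize(m.loc[kept, "s"].to_numpy(), ref, scale)
    m.attrs["reference_total"] = ref
    return m


def daily_totals(metrics: pd.DataFrame, reference_day: int, dates: Sequence[int] | None = None) -> pd.Series:
    """Per-date total SCI over *all* clusters, normalized to the reference
    date's total (reference date maps to 1.0; cluster-free dates to 0)."""
    totals = metrics.groupby("date")["sci"].sum()
    if dates is not None:
        totals = totals.reindex(list(dates), fill_value=0.0)
    if reference_day not in totals.index or not totals.loc[reference_day] > 0:
        raise ValueError(f"reference date {reference_day} absent or empty")
    return totals / totals.loc[reference_day]


def run_pipeline(
    config: PipelineConfig,
    *,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
    world: World | None = None,
    records: pd.DataFrame | None = None,
    with_outputs: bool = True,
) -> RunResult:
    """Execute the full pipeline for one parameter setting.

    ``world``/``records`` may be supplied to reuse a simulated stream
    (e.g. across a sensitivity grid); otherwise they are generated from
    the config.
    """
    plans: list[GatheringPlan] = []
    if world is None or records is None:
        world, plans, records = simulate_stream(config)

    clean, log = clean_frame(split_by_arrival(records), world)
    weights = monthly_weights(
        clean, world, lower=config.lower_percentile, upper=config.upper_percentile
    )
    stats = cluster_stats(clean, world, weights, config.params)
    metrics = finalize_metrics(
        stats, config.params.contact_threshold, config.reference_day, config.scale
    )
    sim = config.simulation
    run_dates = range(sim.start_day, sim.start_day + sim.days)
    daily = daily_totals(metrics, config.reference_day, dates=run_dates)

    if with_outputs:
        overlaps = cluster_poi_overlaps(metrics, world)
        poi_day = aggregate(metrics, overlaps, world)
    else:
        poi_day = pd.DataFrame()

    manifest = config.manifest()
    manifest["ingest"] = log.as_dict()
    manifest["n_clusters"] = int(len(metrics))
    manifest["reference_total_person_minutes"] = metrics.attrs["reference_total"]
    result = RunResult(
        config=config,
        world=world,
        records=records,
        clean=clean,
        ingest_log=log,
        weights=weights,
        metrics=metrics,
        poi_day=poi_day,
        daily=daily,
        plans=plans,
        manifest=manifest,
    )
    if out_dir is not None:
        result.write(out_dir, overwrite=overwrite)
    return result


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p-value."""
    r, p = sps.pearsonr(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return float(r), float(p)


def sensitivity(
    config: PipelineConfig,
    *,
    grid: Sequence[tuple[float, float]] = SENSITIVITY_GRID,
    baseline: tuple[float, float] = BASELINE_PARAMS,
    world: World | None = None,
    records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Daily-total SCI correlation between the baseline parameters and each
    (eps_space, C) grid pair, on one shared record stream.

    Clustering is recomputed per distinct eps_space (the contact threshold
    only affects the per-cluster arithmetic).  Returns one row per pair:
    eps_space, contact_threshold, pearson_r, p_value — the baseline row has
    r = 1 exactly.
    """
    if world is None or records is None:
        world, _, records = simulate_stream(config)
    sim = config.simulation
    if sim.days < 3:
        raise ValueError("need at least 3 dates for a correlation")
    clean, _ = clean_frame(split_by_arrival(records), world)
    weights = monthly_weights(
        clean, world, lower=config.lower_percentile, upper=config.upper_percentile
    )
    run_dates = range(sim.start_day, sim.start_day + sim.days)

    stats_by_eps: dict[float, pd.DataFrame] = {}

    def series_for(eps_space: float, c: float) -> pd.Series:
        if eps_space not in stats_by_eps:
            params = dataclasses.replace(config.params, eps_space=eps_space)
            stats_by_eps[eps_space] = cluster_stats(clean, world, weights, params)
        m = finalize_metrics(stats_by_eps[eps_space], c, config.reference_day, config.scale)
        return daily_totals(m, config.reference_day, dates=run_dates)

    base = series_for(*baseline)
    rows = [(baseline[0], baseline[1], 1.0, 0.0)]
    for eps_space, c in grid:
        if (eps_space, c) == tuple(baseline):
            continue
        series = series_for(eps_space, c)
        r, p = pearson(base.to_numpy(), series.to_numpy())
        rows.append((eps_space, c, r, p))
    return pd.DataFrame(
        rows, columns=["eps_space", "contact_threshold", "pearson_r", "p_value"]
    )
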