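"""Reference study scenarios on the synthetic world.

These are the canonical simulated experiments the package ships with:

* :func:`sensitivity_study` — a month-long, 2000-user run with isolated
  planted gatherings, evaluated over the (eps_space, C) sensitivity grid
  against the (15 m, 15 m) baseline; also reports the reference-date
  normalization identity.
* :func:`gathering_recovery_study` — 50 isolated gatherings planted over
  five days; measures how many are recovered as exactly one cluster and
  how well each cluster's estimated person count matches the planted
  participants times the known person-per-user sampling ratio.
* :func:`cadence_study` — the observed mean records per user per day.

Each scenario is deterministic for a fixed seed and scaled so the full
set runs on a single CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import (
    PipelineConfig,
    SimulationConfig,
    run_pipeline,
    sensitivity,
    simulate_stream,
)
from .simulate import GatheringConfig, GatheringPlan, generate_records
from .world import WorldConfig, generate_world


def sensitivity_config(seed: int, *, n_users: int = 2000, days: int = 30) -> PipelineConfig:
    """Study conditions for the sensitivity grid: default world geometry,
    2000 users, 30 days, gatherings isolated by the world's 200 m POI
    separation with spreads at or below 7 m and 12+ participants."""
    return PipelineConfig(
        world=WorldConfig(n_users=n_users),
        simulation=SimulationConfig(
            days=days,
            gatherings=GatheringConfig(
                mean_per_day=8.0,
                weekly_amplitude=0.5,
                participants=(12, 24),
                duration_min=(40.0, 90.0),
                spread_m=(3.0, 7.0),
            ),
        ),
        seed=seed,
    )


@dataclass
class SensitivityStudy:
    grid: pd.DataFrame  # eps_space, contact_threshold, pearson_r, p_value
    reference_day_sci_total: float  # sum of SCI over the reference date
    n_days: int
    n_clusters_baseline: int
    baseline_daily: pd.Series = field(repr=False, default=None)


def sensitivity_study(seed: int, *, n_users: int = 2000, days: int = 30) -> SensitivityStudy:
    """Run the sensitivity grid on one shared synthetic stream."""
    config = sensitivity_config(seed, n_users=n_users, days=days)
    world, _, records = simulate_stream(config)
    grid = sensitivity(config, world=world, records=records)
    base = run_pipeline(config, world=world, records=records, with_outputs=False)
    ref_total = float(
        base.metrics.loc[base.metrics["date"] == config.reference_day, "sci"].sum()
    )
    return SensitivityStudy(
        grid=grid,
        reference_day_sci_total=ref_total,
        n_days=days,
        n_clusters_baseline=int(len(base.metrics)),
        baseline_daily=base.daily,
    )


@dataclass
class GatheringRecovery:
    n_planted: int
    n_recovered_once: int  # gatherings matched by exactly one cluster
    cluster_counts: list[int]  # matching clusters per gathering
    n_errors: list[float]  # relative error of N vs participants * ratio
    sampling_ratio: float


def recovery_config(seed: int, *, n_users: int = 2000) -> PipelineConfig:
    """Five days with ten gatherings per day at distinct POIs, 14-22
    participants each, <= 7 m spread, >= 40 min.

    The stage is a sparser 6x6 world with ~3 km CBG cells: person-count
    recovery compares each cluster's estimated persons against the planted
    participants alone, so the uniform background scatter must be thin
    enough that passersby rarely brush the isolated gatherings, while the
    user base stays large enough (~55 users per CBG) for stable
    persons-per-user weights.
    """
    return PipelineConfig(
        world=WorldConfig(
            grid_rows=6,
            grid_cols=6,
            cbg_lat_deg=0.03,
            cbg_lon_deg=0.0345,
            zcta_rows=3,
            zcta_cols=3,
            n_users=n_users,
        ),
        simulation=SimulationConfig(
            days=5,
            gatherings=GatheringConfig(
                participants=(14, 22),
                duration_min=(40.0, 80.0),
                spread_m=(3.0, 7.0),
            ),
            gatherings_per_day=10,
            daily_activity=1.0,  # full panel: recovery compares against planted truth
        ),
        seed=seed,
    )


def _match_clusters(metrics: pd.DataFrame, plan: GatheringPlan, world) -> pd.DataFrame:
    """Clusters on the plan's date whose bbox center falls within twice the
    POI radius (POIs are isolated by >= 200 m, so matches are unambiguous)
    and whose time span intersects the plan window."""
    poi = world.poi_by_id(plan.poi_id)
    sel = metrics.loc[metrics["date"] == plan.day].copy()
    if len(sel) == 0:
        return sel
    from .geometry import project

    cx = 0.5 * (sel["x_min"] + sel["x_max"])
    cy = 0.5 * (sel["y_min"] + sel["y_max"])
    # project the POI into each cluster's frame (origins differ per CBG)
    px = np.empty(len(sel))
    py = np.empty(len(sel))
    for i, (olat, olon) in enumerate(zip(sel["origin_lat"], sel["origin_lon"])):
        x, y = project(poi.lat, poi.lon, olat, olon)
        px[i], py[i] = float(x), float(y)
    dist = np.hypot(cx.to_numpy() - px, cy.to_numpy() - py)
    near = dist <= max(2.0 * poi.radius_m, 60.0)
    # time overlap with the plan window, in absolute minutes
    offset = world.default_utc_offset_min
    w0 = plan.day * 1440.0 + plan.start_min - offset
    w1 = plan.day * 1440.0 + plan.end_min - offset
    t0 = sel["t_min"].to_numpy()
    t1 = sel["t_max"].to_numpy()
    overlap = (t0 <= w1) & (t1 >= w0)
    return sel.loc[near & overlap]


def gathering_recovery_study(seed: int, *, n_users: int = 2000) -> GatheringRecovery:
    config = recovery_config(seed, n_users=n_users)
    world, plans, records = simulate_stream(config)
    result = run_pipeline(config, world=world, records=records, with_outputs=False)
    ratio = float(world.cbg_populations.sum()) / len(world.users)
    counts = []
    errors = []
    for plan in plans:
        matches = _match_clusters(result.metrics, plan, world)
        counts.append(int(len(matches)))
        if len(matches) == 1:
            n_est = float(matches["n_persons"].iloc[0])
            expected = len(plan.user_ids) * ratio
            errors.append(abs(n_est - expected) / expected)
    return GatheringRecovery(
        n_planted=len(plans),
        n_recovered_once=sum(1 for c in counts if c == 1),
        cluster_counts=counts,
        n_errors=errors,
        sampling_ratio=ratio,
    )


def cadence_study(seed: int, *, n_users: int = 1000, cadence: float = 120.0) -> float:
    """Observed mean records per active user per day on one simulated day.

    Users whose phone contributed nothing that day (panel churn) are not
    part of the denominator: the feed's stated cadence is per reporting
    user.
    """
    world = generate_world(WorldConfig(n_users=n_users), seed)
    records = generate_records(
        world, [], 1, start_day=18262, cadence_per_day=cadence, seed=seed + 1
    )
    return len(records) / records["user_id"].nunique()
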