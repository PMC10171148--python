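"""Plant one gathering and recover it with the spatiotemporal DBSCAN.

Fifteen users meet at a POI for an hour; their records relocate to a
5 m spread about the POI center.  Clustering the POI's CBG partition with
the standard thresholds (15 m, 20 min, M = 10) finds the crowd, and the
exhaustive O(n^2) oracle confirms the same partition.
"""

import datetime as dt

import pandas as pd

from crowdcontact import ClusterParams, WorldConfig, generate_world
from crowdcontact.clustering import dbscan, dbscan_oracle_labels, dbscan_labels
from crowdcontact.geometry import project
from crowdcontact.records import day_number
from crowdcontact.simulate import GatheringPlan, generate_records

world = generate_world(WorldConfig(n_users=400), seed=3)
start = day_number(dt.date(2020, 1, 1))
poi = world.pois[0]
plan = GatheringPlan(
    poi_id=poi.id,
    day=start,
    start_min=13 * 60.0,
    end_min=14 * 60.0,
    user_ids=tuple(u.id for u in world.users[:15]),
    spread_m=5.0,
)
records = generate_records(world, [plan], 1, start_day=start, seed=4, daily_activity=1.0)

# records of the CBG containing the POI, projected about its center
cbg_ix = int(world.cbg_index_of([poi.lat], [poi.lon])[0])
sel = records.loc[world.cbg_index_of(records["lat"], records["lon"]) == cbg_ix]
lat0 = 0.5 * (world._arrays()["lat_min"][cbg_ix] + world._arrays()["lat_max"][cbg_ix])
lon0 = 0.5 * (world._arrays()["lon_min"][cbg_ix] + world._arrays()["lon_max"][cbg_ix])
x, y = project(sel["lat"].to_numpy(), sel["lon"].to_numpy(), lat0, lon0)
points = pd.DataFrame(
    {"x": x, "y": y, "t": sel["timestamp"].to_numpy() / 60.0, "user_id": sel["user_id"]}
)

params = ClusterParams()
clusters = dbscan(points, params)
print(f"partition: {len(points)} records -> {len(clusters)} cluster(s)")
for c in clusters:
    print(
        f"  cluster {c.id}: {c.n_records} records, {c.n_users} users, "
        f"bbox {c.bbox_area:.0f} m^2, duration {c.duration:.0f} min"
    )
# Expect one daytime cluster near the POI: ~15 users for ~60 min, i.e. the
# planted gathering (plus the morning/evening home-centroid crowds).

oracle = dbscan_oracle_labels(
    points["x"].to_numpy(), points["y"].to_numpy(), points["t"].to_numpy(), params
)
fast = dbscan_labels(
    points["x"].to_numpy(), points["y"].to_numpy(), points["t"].to_numpy(), params
)
print("oracle agrees:", (oracle == fast).all())
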