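"""Synthetic geography: census block groups, POIs, ZCTAs and users.

The world is a rectangular grid of census block groups (CBGs), each with a
population and a fixed UTC offset, tiled by larger ZCTA rectangles and
sprinkled with point-of-interest discs.  Users live at the *centroid* of
their home CBG, emulating a vendor feed in which residential coordinates
are obfuscated to the block-group centroid.  Axis-aligned rectangles stand
in for real census shapes so that point-in-region tests are exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    METERS_PER_DEG_LAT,
    Rect,
    haversine_m,
    meters_per_deg_lon,
)


@dataclass(frozen=True)
class CBG:
    id: str
    county: str
    rect: Rect
    population: int
    utc_offset_min: int


@dataclass(frozen=True)
class POI:
    id: str
    type: str
    subtype: str
    lat: float
    lon: float
    radius_m: float
    zcta: str


@dataclass(frozen=True)
class ZCTA:
    code: str  # 5-character code
    rect: Rect


@dataclass(frozen=True)
class User:
    id: str
    home_cbg: str
    home_lat: float
    home_lon: float


@dataclass(frozen=True)
class PoiType:
    type: str
    subtype: str
    radius_m: float


#: default point-of-interest catalogue: (type, subtype, standard radius in m)
DEFAULT_POI_TYPES: tuple[PoiType, ...] = (
    PoiType("Grocery", "Supermarket", 30.0),
    PoiType("Restaurant", "Full_Service_Restaurant", 25.0),
    PoiType("Retail", "Department_Store", 40.0),
    PoiType("Fitness", "Gym", 20.0),
    PoiType("Park", "Playground", 60.0),
)


@dataclass(frozen=True)
class WorldConfig:
    """Knobs for :func:`generate_world`.

    The defaults describe a compact coastal-plain study region: a 6x6 grid
    of roughly 1.1 km square CBGs (36 CBGs, 6 counties of one grid row
    each, nine 2x2-CBG ZCTAs), one POI per CBG, populations of 500-2000,
    and a single Eastern-time UTC offset.
    """

    grid_rows: int = 6
    grid_cols: int = 6
    origin_lat: float = 28.0
    origin_lon: float = -81.5
    cbg_lat_deg: float = 0.010
    cbg_lon_deg: float = 0.0115
    pois_per_cbg: int = 1
    poi_types: tuple[PoiType, ...] = DEFAULT_POI_TYPES
    population_range: tuple[int, int] = (500, 2000)
    n_users: int = 1000
    utc_offset_min: int = -300
    min_poi_separation_m: float = 200.0
    min_poi_home_clearance_m: float = 200.0
    zcta_rows: int = 2
    zcta_cols: int = 2
    region_name: str = "Florida"
    os_labels: tuple[str, ...] = ("ios", "android")
    os_probs: tuple[float, ...] = (0.45, 0.55)

    def with_users(self, n_users: int) -> "WorldConfig":
        return replace(self, n_users=n_users)


@dataclass
class World:
    cbgs: list[CBG]
    pois: list[POI]
    zctas: list[ZCTA]
    users: list[User]
    default_utc_offset_min: int = -300
    region_name: str = "Florida"
    _cache: dict = field(default_factory=dict, repr=False)

    # -- derived arrays -------------------------------------------------
    def _arrays(self) -> dict:
        if "cbg" not in self._cache:
            cbgs = sorted(self.cbgs, key=lambda c: c.id)
            self._cache["cbg"] = {
                "ids": [c.id for c in cbgs],
                "county": [c.county for c in cbgs],
                "lat_min": np.array([c.rect.lat_min for c in cbgs]),
                "lat_max": np.array([c.rect.lat_max for c in cbgs]),
                "lon_min": np.array([c.rect.lon_min for c in cbgs]),
                "lon_max": np.array([c.rect.lon_max for c in cbgs]),
                "population": np.array([c.population for c in cbgs], dtype=np.int64),
                "offset": np.array([c.utc_offset_min for c in cbgs], dtype=np.int64),
            }
        return self._cache["cbg"]

    @property
    def cbg_ids(self) -> list[str]:
        return self._arrays()["ids"]

    @property
    def cbg_populations(self) -> np.ndarray:
        return self._arrays()["population"]

    @property
    def cbg_offsets_min(self) -> np.ndarray:
        return self._arrays()["offset"]

    @property
    def counties(self) -> list[str]:
        return self._arrays()["county"]

    @property
    def bounds(self) -> Rect:
        a = self._arrays()
        return Rect(
            float(a["lat_min"].min()),
            float(a["lat_max"].max()),
            float(a["lon_min"].min()),
            float(a["lon_max"].max()),
        )

    @property
    def census(self) -> pd.Series:
        """cbg id -> population."""
        a = self._arrays()
        return pd.Series(a["population"], index=pd.Index(a["ids"], name="cbg_id"))

    def cbg_index_of(self, lat, lon) -> np.ndarray:
        """Index (into sorted ``cbg_ids``) of the CBG containing each point.

        Points on a shared edge go to the lexicographically smallest CBG id;
        points in no CBG get -1.
        """
        a = self._arrays()
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        out = np.full(lat.shape, -1, dtype=np.int32)
        unset = np.ones(lat.shape, dtype=bool)
        for i in range(len(a["ids"])):
            m = (
                unset
                & (lat >= a["lat_min"][i])
                & (lat <= a["lat_max"][i])
                & (lon >= a["lon_min"][i])
                & (lon <= a["lon_max"][i])
            )
            out[m] = i
            unset &= ~m
            if not unset.any():
                break
        return out

    def zcta_of(self, lat: float, lon: float) -> str | None:
        hits = [z.code for z in sorted(self.zctas, key=lambda z: z.code) if z.rect.contains(lat, lon)]
        return hits[0] if hits else None

    def user_home_indices(self) -> np.ndarray:
        """Per-user index of the home CBG into sorted ``cbg_ids``."""
        if "user_home_ix" not in self._cache:
            pos = {cid: i for i, cid in enumerate(self.cbg_ids)}
            self._cache["user_home_ix"] = np.array(
                [pos[u.home_cbg] for u in self.users], dtype=np.int32
            )
        return self._cache["user_home_ix"]

    def poi_by_id(self, poi_id: str) -> POI:
        if "poi_map" not in self._cache:
            self._cache["poi_map"] = {p.id: p for p in self.pois}
        return self._cache["poi_map"][poi_id]

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if not self.cbgs:
            raise ValueError("world has no CBGs")
        for c in self.cbgs:
            if c.population <= 0:
                raise ValueError(f"CBG {c.id} has non-positive population")
        ids = [c.id for c in self.cbgs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate CBG ids")
        for a, b in itertools.combinations(self.cbgs, 2):
            if (
                a.rect.lat_min < b.rect.lat_max
                and b.rect.lat_min < a.rect.lat_max
                and a.rect.lon_min < b.rect.lon_max
                and b.rect.lon_min < a.rect.lon_max
            ):
                raise ValueError(f"CBG rectangles {a.id} and {b.id} overlap")
        for p in self.pois:
            hits = [z.code for z in self.zctas if z.rect.contains(p.lat, p.lon)]
            if len(hits) == 0:
                raise ValueError(f"POI {p.id} lies in no ZCTA")
        known = set(c.id for c in self.cbgs)
        for u in self.users:
            if u.home_cbg not in known:
                raise ValueError(f"user {u.id} has unknown home CBG {u.home_cbg}")

    # -- persistence ----------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                (c.id, c.county, c.rect.lat_min, c.rect.lat_max, c.rect.lon_min,
                 c.rect.lon_max, c.population, c.utc_offset_min)
                for c in self.cbgs
            ],
            columns=["cbg_id", "county", "lat_min", "lat_max", "lon_min", "lon_max",
                     "population", "utc_offset_min"],
        ).to_csv(out / "cbgs.csv", index=False, float_format="%.17g")
        pd.DataFrame(
            [(p.id, p.type, p.subtype, p.lat, p.lon, p.radius_m, p.zcta) for p in self.pois],
            columns=["poi_id", "poi_type", "poi_subtype", "lat", "lon", "radius_m", "zcta"],
        ).to_csv(out / "pois.csv", index=False, float_format="%.17g")
        pd.DataFrame(
            [(z.code, z.rect.lat_min, z.rect.lat_max, z.rect.lon_min, z.rect.lon_max)
             for z in self.zctas],
            columns=["zcta", "lat_min", "lat_max", "lon_min", "lon_max"],
        ).to_csv(out / "zctas.csv", index=False, float_format="%.17g")
        pd.DataFrame(
            [(c.id, c.population) for c in self.cbgs], columns=["cbg_id", "population"]
        ).to_csv(out / "census.csv", index=False)
        pd.DataFrame(
            [(u.id, u.home_cbg, u.home_lat, u.home_lon) for u in self.users],
            columns=["user_id", "home_cbg", "home_lat", "home_lon"],
        ).to_csv(out / "users.csv", index=False, float_format="%.17g")
        pd.DataFrame(
            [(self.region_name, self.default_utc_offset_min)],
            columns=["region_name", "default_utc_offset_min"],
        ).to_csv(out / "meta.csv", index=False)

    @classmethod
    def load(cls, in_dir: str | Path) -> "World":
        src = Path(in_dir)
        cbgs = [
            CBG(r.cbg_id, r.county, Rect(r.lat_min, r.lat_max, r.lon_min, r.lon_max),
                int(r.population), int(r.utc_offset_min))
            for r in pd.read_csv(src / "cbgs.csv", dtype={"cbg_id": str, "county": str}, float_precision="round_trip").itertuples()
        ]
        pois = [
            POI(r.poi_id, r.poi_type, r.poi_subtype, r.lat, r.lon, r.radius_m, str(r.zcta))
            for r in pd.read_csv(src / "pois.csv", dtype={"poi_id": str, "zcta": str}, float_precision="round_trip").itertuples()
        ]
        zctas = [
            ZCTA(str(r.zcta), Rect(r.lat_min, r.lat_max, r.lon_min, r.lon_max))
            for r in pd.read_csv(src / "zctas.csv", dtype={"zcta": str}, float_precision="round_trip").itertuples()
        ]
        users = [
            User(r.user_id, r.home_cbg, r.home_lat, r.home_lon)
            for r in pd.read_csv(src / "users.csv", dtype={"user_id": str, "home_cbg": str}, float_precision="round_trip").itertuples()
        ]
        meta = pd.read_csv(src / "meta.csv")
        world = cls(cbgs, pois, zctas, users,
                    default_utc_offset_min=int(meta.default_utc_offset_min[0]),
                    region_name=str(meta.region_name[0]))
        world.validate()
        return world


def generate_world(config: WorldConfig, seed: int) -> World:
    """Deterministically generate a synthetic :class:`World`.

    CBGs tile a rectangle; POIs are rejection-sampled inside their CBG with
    a minimum pairwise separation and a minimum clearance from every CBG
    centroid (the planted home locations), so that planted gatherings are
    spatially isolated from the obfuscated-home point mass.
    """
    if config.grid_rows <= 0 or config.grid_cols <= 0:
        raise ValueError("grid dimensions must be positive")
    if config.pois_per_cbg < 0 or config.n_users <= 0:
        raise ValueError("counts must be positive")
    if any(t.radius_m <= 0 for t in config.poi_types):
        raise ValueError("POI radii must be positive")
    lo, hi = config.population_range
    if lo <= 0 or hi < lo:
        raise ValueError("population range must be positive and ordered")

    rng = np.random.default_rng(seed)

    cbgs: list[CBG] = []
    for r in range(config.grid_rows):
        for c in range(config.grid_cols):
            rect = Rect(
                config.origin_lat + r * config.cbg_lat_deg,
                config.origin_lat + (r + 1) * config.cbg_lat_deg,
                config.origin_lon + c * config.cbg_lon_deg,
                config.origin_lon + (c + 1) * config.cbg_lon_deg,
            )
            cbgs.append(
                CBG(
                    id=f"cbg{r:02d}{c:02d}",
                    county=f"cty{r:02d}",
                    rect=rect,
                    population=int(rng.integers(lo, hi + 1)),
                    utc_offset_min=config.utc_offset_min,
                )
            )

    zctas: list[ZCTA] = []
    n_zr = -(-config.grid_rows // config.zcta_rows)
    n_zc = -(-config.grid_cols // config.zcta_cols)
    k = 0
    for zr in range(n_zr):
        for zc in range(n_zc):
            r0, r1 = zr * config.zcta_rows, min((zr + 1) * config.zcta_rows, config.grid_rows)
            c0, c1 = zc * config.zcta_cols, min((zc + 1) * config.zcta_cols, config.grid_cols)
            zctas.append(
                ZCTA(
                    code=f"33{k:03d}",
                    rect=Rect(
                        config.origin_lat + r0 * config.cbg_lat_deg,
                        config.origin_lat + r1 * config.cbg_lat_deg,
                        config.origin_lon + c0 * config.cbg_lon_deg,
                        config.origin_lon + c1 * config.cbg_lon_deg,
                    ),
                )
            )
            k += 1

    centroids = [c.rect.center for c in cbgs]
    pois: list[POI] = []
    type_cycle = itertools.cycle(config.poi_types)
    world_stub = World(cbgs, [], zctas, [], config.utc_offset_min, config.region_name)
    for cbg in cbgs:
        for _ in range(config.pois_per_cbg):
            ptype = next(type_cycle)
            margin_lat = ptype.radius_m / METERS_PER_DEG_LAT
            margin_lon = ptype.radius_m / meters_per_deg_lon(config.origin_lat)
            placed = False
            for _try in range(2000):
                lat = rng.uniform(cbg.rect.lat_min + margin_lat, cbg.rect.lat_max - margin_lat)
                lon = rng.uniform(cbg.rect.lon_min + margin_lon, cbg.rect.lon_max - margin_lon)
                if pois and float(
                    min(haversine_m(lat, lon, p.lat, p.lon) for p in pois)
                ) < config.min_poi_separation_m:
                    continue
                if float(
                    min(haversine_m(lat, lon, clat, clon) for clat, clon in centroids)
                ) < config.min_poi_home_clearance_m:
                    continue
                placed = True
                break
            if not placed:
                raise ValueError("could not place POI under separation constraints")
            zcode = world_stub.zcta_of(lat, lon)
            pois.append(
                POI(
                    id=f"poi{len(pois):04d}",
                    type=ptype.type,
                    subtype=ptype.subtype,
                    lat=float(lat),
                    lon=float(lon),
                    radius_m=float(ptype.radius_m),
                    zcta=str(zcode),
                )
            )

    pops = np.array([c.population for c in cbgs], dtype=float)
    home_ix = rng.choice(len(cbgs), size=config.n_users, p=pops / pops.sum())
    users = [
        User(
            id=f"u{i:05d}",
            home_cbg=cbgs[j].id,
            home_lat=centroids[j][0],
            home_lon=centroids[j][1],
        )
        for i, j in enumerate(home_ix)
    ]

    world = World(cbgs, pois, zctas, users, config.utc_offset_min, config.region_name)
    world.validate()
    return world
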