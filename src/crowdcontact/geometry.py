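"""Planar geometry helpers shared across the pipeline.

All clustering and contact arithmetic happens in a local equirectangular
projection about a per-partition origin: at the sub-kilometre scale of a
census block group the projection error relative to great-circle distance
is far below the ~10 m accuracy of the input records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6371008.8  # mean Earth radius
_DEG = math.pi / 180.0
METERS_PER_DEG_LAT = EARTH_RADIUS_M * _DEG


def meters_per_deg_lon(lat_deg: float) -> float:
    return METERS_PER_DEG_LAT * math.cos(lat_deg * _DEG)


def project(lat, lon, lat0: float, lon0: float):
    """Equirectangular projection to meters about (lat0, lon0).

    x = R * dlon * cos(lat0), y = R * dlat (angles in radians). Linear in
    the coordinates, hence exactly invertible by :func:`unproject`.
    """
    x = (np.asarray(lon, dtype=float) - lon0) * meters_per_deg_lon(lat0)
    y = (np.asarray(lat, dtype=float) - lat0) * METERS_PER_DEG_LAT
    return x, y


def unproject(x, y, lat0: float, lon0: float):
    lat = np.asarray(y, dtype=float) / METERS_PER_DEG_LAT + lat0
    lon = np.asarray(x, dtype=float) / meters_per_deg_lon(lat0) + lon0
    return lat, lon


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters (used as the projection oracle)."""
    p1 = np.asarray(lat1, dtype=float) * _DEG
    p2 = np.asarray(lat2, dtype=float) * _DEG
    dphi = p2 - p1
    dlmb = (np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float)) * _DEG
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


@dataclass(frozen=True)
class Rect:
    """Axis-aligned lat/lon rectangle, boundary inclusive."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError(f"degenerate rectangle: {self}")

    def contains(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        return (
            (lat >= self.lat_min)
            & (lat <= self.lat_max)
            & (lon >= self.lon_min)
            & (lon <= self.lon_max)
        )

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.lat_min + self.lat_max), 0.5 * (self.lon_min + self.lon_max))


def circle_rect_overlap_area(
    cx: float, cy: float, r: float, x0: float, y0: float, x1: float, y1: float
) -> float:
    """Exact area of the intersection of a disc with an axis-aligned box.

    Decomposes the box into four signed corner rectangles anchored at the
    disc center; each corner area is a closed-form mix of a rectangle and a
    circular segment.  Inputs are planar meters.
    """
    if r <= 0.0:
        return 0.0

    def _g(x: float, h: float) -> float:
        # area of disc(0, r) ∩ [0, x] × [0, h], with x, h >= 0
        x = min(x, r)
        h = min(h, r)
        if x <= 0.0 or h <= 0.0:
            return 0.0
        u0 = math.sqrt(max(r * r - h * h, 0.0))
        if x <= u0:
            return x * h

        def F(u: float) -> float:
            u = min(max(u, -r), r)
            return 0.5 * (u * math.sqrt(max(r * r - u * u, 0.0)) + r * r * math.asin(u / r))

        return u0 * h + F(x) - F(u0)

    def _w(x: float, y: float) -> float:
        sign = 1.0
        if x < 0.0:
            sign, x = -sign, -x
        if y < 0.0:
            sign, y = -sign, -y
        return sign * _g(x, y)

    ax0, ax1 = x0 - cx, x1 - cx
    ay0, ay1 = y0 - cy, y1 - cy
    area = _w(ax1, ay1) - _w(ax0, ay1) - _w(ax1, ay0) + _w(ax0, ay0)
    return max(area, 0.0)
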