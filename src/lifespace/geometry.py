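"""Spatial extent measures over stay nodes and GPS paths.

Planar work (hulls, ellipses, buffers) runs in a local equirectangular
projection centred on the input points: at city scale (tens of km near the
equator) its area distortion is far below measurement noise, and it keeps the
geometry stack to shapely + numpy.  Great-circle distances use the haversine
formula with a 6371 km Earth radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import Delaunay
from shapely.geometry import LineString, MultiPoint, Point, Polygon, mapping
from shapely.ops import unary_union

EARTH_RADIUS_M = 6_371_000.0
_DEG = math.pi / 180.0


def geodesic_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle (haversine) distance in meters."""
    phi1, phi2 = lat1 * _DEG, lat2 * _DEG
    dphi = (lat2 - lat1) * _DEG
    dlam = (lon2 - lon1) * _DEG
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


@dataclass(frozen=True)
class ProjectionContext:
    """Local equirectangular projection: meters east/north of an origin.

    Longitude is scaled by cos(origin latitude).  Inverse(project(p)) == p to
    well below 1e-9 degrees.
    """

    origin_lat: float
    origin_lon: float

    @classmethod
    def for_points(cls, lats: Sequence[float], lons: Sequence[float]) -> "ProjectionContext":
        return cls(float(np.mean(lats)), float(np.mean(lons)))

    @property
    def m_per_deg_lat(self) -> float:
        return EARTH_RADIUS_M * _DEG

    @property
    def m_per_deg_lon(self) -> float:
        return EARTH_RADIUS_M * _DEG * math.cos(self.origin_lat * _DEG)

    def project(self, lat, lon):
        """Degrees -> local (x, y) meters; accepts scalars or arrays."""
        x = (np.asarray(lon) - self.origin_lon) * self.m_per_deg_lon
        y = (np.asarray(lat) - self.origin_lat) * self.m_per_deg_lat
        return x, y

    def inverse(self, x, y):
        lat = np.asarray(y) / self.m_per_deg_lat + self.origin_lat
        lon = np.asarray(x) / self.m_per_deg_lon + self.origin_lon
        return lat, lon


@dataclass(frozen=True)
class ExtentConfig:
    path_buffer_m: float = 100.0
    concave_alpha_m: float = 500.0
    duration_weighted: bool = False

    def __post_init__(self) -> None:
        if self.path_buffer_m <= 0 or self.concave_alpha_m <= 0:
            raise ValueError("buffer and alpha must be positive")


@dataclass
class HullResult:
    area_km2: float
    polygon: Polygon | None
    degenerate: bool

    def __geo_interface__(self):
        return mapping(self.polygon) if self.polygon is not None else None


@dataclass
class EllipseResult:
    center_lat: float
    center_lon: float
    sigma1_m: float
    sigma2_m: float
    theta_deg: float
    area_km2: float
    degenerate: bool = False


def nodes_within_radius(points: Iterable[tuple[float, float]],
                        center: tuple[float, float], radius_m: float) -> int:
    """Count points with geodesic distance <= radius_m of center (inclusive)."""
    clat, clon = center
    return sum(1 for lat, lon in points if geodesic_m(lat, lon, clat, clon) <= radius_m)


def _projected(points: Sequence[tuple[float, float]]) -> tuple[np.ndarray, ProjectionContext]:
    pts = np.asarray(points, dtype=float)
    ctx = ProjectionContext.for_points(pts[:, 0], pts[:, 1])
    x, y = ctx.project(pts[:, 0], pts[:, 1])
    return np.column_stack([x, y]), ctx


def hull_area_km2(points: Sequence[tuple[float, float]], mode: str = "convex",
                  cfg: ExtentConfig = ExtentConfig()) -> HullResult:
    """Area of the convex hull or alpha-shape concave hull of (lat, lon) points.

    Fewer than 3 non-collinear points yield area 0 with the degenerate flag.
    """
    if mode not in ("convex", "concave"):
        raise ValueError(f"unknown hull mode {mode!r}")
    if len(points) < 3:
        return HullResult(0.0, None, True)
    xy, _ = _projected(points)
    if mode == "convex":
        hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    else:
        hull = alpha_shape(xy, cfg.concave_alpha_m)
    if hull.is_empty or hull.area == 0.0:
        return HullResult(0.0, None, True)
    poly = hull if isinstance(hull, Polygon) else hull.convex_hull if mode == "convex" else hull
    return HullResult(hull.area / 1e6, poly if isinstance(poly, Polygon) else None, False)


def alpha_shape(xy: np.ndarray, alpha_m: float):
    """Alpha-shape: union of Delaunay triangles with circumradius <= alpha_m."""
    if len(xy) < 3:
        return MultiPoint([tuple(p) for p in xy]).convex_hull
    try:
        tri = Delaunay(xy)
    except Exception:  # collinear input
        return MultiPoint([tuple(p) for p in xy]).convex_hull
    keep = []
    for simplex in tri.simplices:
        a, b, c = xy[simplex]
        r = _circumradius(a, b, c)
        if r <= alpha_m:
            keep.append(Polygon([a, b, c]))
    if not keep:
        return Polygon()
    return unary_union(keep)


def _circumradius(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c), np.linalg.norm(a - b))
    area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
    if area2 == 0:
        return math.inf
    return la * lb * lc / (2 * area2)


def sd_ellipse(points: Sequence[tuple[float, float]],
               weights: Sequence[float] | None = None) -> EllipseResult:
    """Standard deviational ellipse of (lat, lon) points.

    Population (divide-by-total-weight) covariance of the locally projected
    points; sigma1/sigma2 are the square roots of its eigenvalues, theta the
    bearing of the major axis measured counterclockwise from east, and
    area = pi * sigma1 * sigma2.
    """
    if len(points) < 3:
        center = np.mean(np.asarray(points, dtype=float), axis=0) if points else (math.nan, math.nan)
        return EllipseResult(float(center[0]), float(center[1]), 0.0, 0.0, 0.0, 0.0, True)
    xy, ctx = _projected(points)
    w = np.ones(len(xy)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    mean = w @ xy
    centered = xy - mean
    cov = (centered * w[:, None]).T @ centered
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    sigma2, sigma1 = math.sqrt(evals[0]), math.sqrt(evals[1])
    major = evecs[:, 1]
    theta = math.degrees(math.atan2(major[1], major[0])) % 180.0
    area_km2 = math.pi * sigma1 * sigma2 / 1e6
    clat, clon = ctx.inverse(mean[0], mean[1])
    degenerate = sigma2 == 0.0
    return EllipseResult(float(clat), float(clon), sigma1, sigma2, theta,
                         area_km2, degenerate)


def daily_path_area_km2(paths: Sequence[Sequence[tuple[float, float]]],
                        cfg: ExtentConfig = ExtentConfig()) -> float:
    """Union area of each path polyline buffered by cfg.path_buffer_m, in km^2.

    Overlapping buffers are not double-counted.  Paths with a single point
    contribute a disc; empty input yields 0.
    """
    all_pts = [p for path in paths for p in path]
    if not all_pts:
        return 0.0
    ctx = ProjectionContext.for_points([p[0] for p in all_pts], [p[1] for p in all_pts])
    geoms = []
    for path in paths:
        if not path:
            continue
        x, y = ctx.project([p[0] for p in path], [p[1] for p in path])
        coords = list(zip(np.atleast_1d(x), np.atleast_1d(y)))
        geom = Point(coords[0]) if len(coords) == 1 else LineString(coords)
        geoms.append(geom.buffer(cfg.path_buffer_m, quad_segs=64))
    if not geoms:
        return 0.0
    return unary_union(geoms).area / 1e6


def radius_of_gyration_m(points: Sequence[tuple[float, float]],
                         weights: Sequence[float] | None = None) -> float:
    """Root-mean-square geodesic distance of points from their (weighted) centroid.

    Rg = sqrt( sum w_i d_i^2 / sum w_i ).  A single point gives 0.
    """
    if not points:
        raise ValueError("radius_of_gyration_m needs at least one point")
    pts = np.asarray(points, dtype=float)
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive total")
    ctx = ProjectionContext.for_points(pts[:, 0], pts[:, 1])
    x, y = ctx.project(pts[:, 0], pts[:, 1])
    cx, cy = np.average(x, weights=w), np.average(y, weights=w)
    clat, clon = ctx.inverse(cx, cy)
    d2 = np.array([geodesic_m(lat, lon, float(clat), float(clon)) ** 2
                   for lat, lon in pts])
    return float(math.sqrt(np.average(d2, weights=w)))
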