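"""Home meso-environment metrics from point layers: nearest-amenity
distances, 1-km buffer counts, and a public transport accessibility level
(PTAL).

The PTAL follows the London-methodology arithmetic — walk time to each
in-range stop, average wait time from headway plus a reliability penalty,
equivalent doorstep frequency EDF = 30 / (walk_min + AWT), per-mode
accessibility index = best EDF + 0.5 x the rest — with every constant
exposed in :class:`PtalConfig` so a local calibration can replace the
defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .geometry import geodesic_m


@dataclass(frozen=True)
class AmenityLayer:
    layer_name: str
    points: tuple[tuple[float, float], ...]
    feature_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.layer_name:
            raise ValueError("layer_name must be nonempty")
        for lat, lon in self.points:
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise ValueError(f"invalid coordinate in layer {self.layer_name}")

    @classmethod
    def from_geojson(cls, layer_name: str, source) -> "AmenityLayer":
        obj = _load_geojson(source)
        pts, ids = [], []
        for i, feat in enumerate(obj.get("features", [])):
            geom = feat.get("geometry") or {}
            if geom.get("type") == "Point":
                lon, lat = geom["coordinates"][:2]
                pts.append((lat, lon))
                ids.append(str(feat.get("id", feat.get("properties", {}).get("id", i))))
        return cls(layer_name=layer_name, points=tuple(pts), feature_ids=tuple(ids))


@dataclass(frozen=True)
class RouteService:
    route_id: str
    headway_min: float

    def __post_init__(self) -> None:
        if self.headway_min <= 0:
            raise ValueError("headway_min must be positive")


@dataclass(frozen=True)
class TransitStop:
    stop_id: str
    lat: float
    lon: float
    mode: str  # "bus" | "rail"
    routes: tuple[RouteService, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("bus", "rail"):
            raise ValueError(f"transit mode must be bus or rail, got {self.mode!r}")


def transit_stops_from_geojson(source) -> list[TransitStop]:
    obj = _load_geojson(source)
    stops = []
    for i, feat in enumerate(obj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            continue
        lon, lat = geom["coordinates"][:2]
        props = feat.get("properties", {})
        routes = tuple(RouteService(str(r["route_id"]), float(r["headway_min"]))
                       for r in props.get("routes", []))
        stops.append(TransitStop(stop_id=str(props.get("stop_id", i)), lat=lat, lon=lon,
                                 mode=props.get("mode", "bus"), routes=routes))
    return stops


def _load_geojson(source) -> dict:
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        return json.loads(Path(source).read_text())
    if isinstance(source, str):
        return json.loads(source)
    if isinstance(source, dict):
        return source
    return json.load(source)


@dataclass(frozen=True)
class PtalConfig:
    walk_speed_m_per_min: float = 80.0
    max_walk_m: Mapping[str, float] = field(
        default_factory=lambda: {"bus": 640.0, "rail": 960.0})
    reliability_min: Mapping[str, float] = field(
        default_factory=lambda: {"bus": 2.0, "rail": 0.75})
    level_band_edges: tuple[float, ...] = (2.5, 5.0, 10.0, 15.0, 20.0)

    def __post_init__(self) -> None:
        if self.walk_speed_m_per_min <= 0:
            raise ValueError("walk_speed_m_per_min must be positive")
        if len(self.level_band_edges) != 5 or list(self.level_band_edges) != sorted(self.level_band_edges):
            raise ValueError("level_band_edges must be 5 ascending values (6 levels)")


@dataclass
class PtalResult:
    access_index: float
    level: int
    per_mode: dict[str, dict]


def nearest_amenity_m(home: tuple[float, float], layer: AmenityLayer
                      ) -> tuple[float, str] | None:
    """Minimum geodesic distance from home to a layer feature, with its id.
    Empty layer -> None (absent, not zero)."""
    if not layer.points:
        return None
    best_i = min(range(len(layer.points)),
                 key=lambda i: geodesic_m(home[0], home[1], *layer.points[i]))
    d = geodesic_m(home[0], home[1], *layer.points[best_i])
    fid = layer.feature_ids[best_i] if layer.feature_ids else str(best_i)
    return d, fid


def buffer_counts(home: tuple[float, float], layers: Sequence[AmenityLayer],
                  radius_m: float = 1000.0) -> dict[str, int]:
    """Per-layer count of features within radius_m of home (boundary inclusive)."""
    return {
        layer.layer_name: sum(
            1 for p in layer.points
            if geodesic_m(home[0], home[1], p[0], p[1]) <= radius_m)
        for layer in layers
    }


def ptal(home: tuple[float, float], stops: Sequence[TransitStop],
         cfg: PtalConfig = PtalConfig()) -> PtalResult:
    """Public transport accessibility of a home point.

    Each route is served from its nearest in-range stop.  Per mode the
    accessibility index is the best route EDF plus half of every other
    route's EDF; the total access index is summed over modes and banded to
    a level 1-6.
    """
    # best (largest EDF) per route per mode
    route_edf: dict[str, dict[str, float]] = {}
    for stop in stops:
        limit = cfg.max_walk_m.get(stop.mode, 0.0)
        d = geodesic_m(home[0], home[1], stop.lat, stop.lon)
        if d > limit:
            continue
        walk_min = d / cfg.walk_speed_m_per_min
        rel = cfg.reliability_min.get(stop.mode, 0.0)
        for route in stop.routes:
            awt = 0.5 * route.headway_min + rel
            edf = 30.0 / (walk_min + awt)
            mode_map = route_edf.setdefault(stop.mode, {})
            if edf > mode_map.get(route.route_id, 0.0):
                mode_map[route.route_id] = edf

    per_mode: dict[str, dict] = {}
    access_index = 0.0
    for mode, edfs in route_edf.items():
        vals = sorted(edfs.values(), reverse=True)
        ai = vals[0] + 0.5 * sum(vals[1:])
        per_mode[mode] = {"edf_by_route": edfs, "access_index": ai}
        access_index += ai

    level = 1
    for edge in cfg.level_band_edges:
        if access_index >= edge:
            level += 1
    return PtalResult(access_index=access_index, level=level, per_mode=per_mode)
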