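"""Trip-side life-space outcomes: counts, mode diversity, durations,
active/passive time shares, mode share by home-distance band, complexity.

A trip belongs to a time segment by its start time (prevents double counting
across the day/night boundary).  Distance bands are half-open intervals of
the geodesic home-to-destination distance, defaulting to [0-2), [2-5),
[5-10), [10, inf) km — the innermost edge reflecting a tolerable walking
distance of about 2 km in a dense city.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import ACTIVE_MODES, StayNode, Trip
from .geometry import geodesic_m
from .nodes import ComplexityConfig, TimeSegment, complexity


@dataclass(frozen=True)
class DistanceBandConfig:
    band_edges_km: tuple[float, ...] = (2.0, 5.0, 10.0)
    collapse_car: bool = False  # merge car_driver/car_passenger into 'car'

    def __post_init__(self) -> None:
        edges = self.band_edges_km
        if not edges or any(e <= 0 for e in edges) or list(edges) != sorted(set(edges)):
            raise ValueError("band edges must be positive and strictly ascending")

    def band_of(self, distance_km: float) -> str:
        lo = 0.0
        for edge in self.band_edges_km:
            if distance_km < edge:
                return f"{_fmt(lo)}-{_fmt(edge)}km"
            lo = edge
        return f"{_fmt(lo)}km+"

    @property
    def band_names(self) -> list[str]:
        names, lo = [], 0.0
        for edge in self.band_edges_km:
            names.append(f"{_fmt(lo)}-{_fmt(edge)}km")
            lo = edge
        names.append(f"{_fmt(lo)}km+")
        return names


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass
class TripCounts:
    trip_count: int
    leg_count: int
    mode_diversity: int
    by_mode: dict[str, int]  # leg counts per mode


@dataclass
class TripDurations:
    total_s: float
    by_mode: dict[str, float]
    active_s: float
    passive_s: float
    active_share: float


def _in_segment(trip: Trip, segment: TimeSegment) -> bool:
    return segment.contains_instant(trip.start_t)


def trip_counts(trips: Sequence[Trip], segment: TimeSegment = TimeSegment()) -> TripCounts:
    by_mode: dict[str, int] = {}
    n_trips = n_legs = 0
    for trip in trips:
        if not _in_segment(trip, segment):
            continue
        n_trips += 1
        for leg in trip.legs:
            n_legs += 1
            by_mode[leg.mode] = by_mode.get(leg.mode, 0) + 1
    return TripCounts(trip_count=n_trips, leg_count=n_legs,
                      mode_diversity=len(by_mode), by_mode=by_mode)


def trip_durations(trips: Sequence[Trip], segment: TimeSegment = TimeSegment()) -> TripDurations:
    by_mode: dict[str, float] = {}
    for trip in trips:
        if not _in_segment(trip, segment):
            continue
        for leg in trip.legs:
            by_mode[leg.mode] = by_mode.get(leg.mode, 0.0) + leg.duration_s
    total = sum(by_mode.values())
    active = sum(v for k, v in by_mode.items() if k in ACTIVE_MODES)
    return TripDurations(total_s=total, by_mode=by_mode, active_s=active,
                         passive_s=total - active,
                         active_share=active / total if total > 0 else 0.0)


def mode_share_by_band(trips: Sequence[Trip], home: StayNode,
                       cfg: DistanceBandConfig = DistanceBandConfig()
                       ) -> dict[str, dict[str, float]]:
    """Share of trips per distance band by the trip's main (longest-leg) mode.

    Band = geodesic home-to-destination distance.  Shares within a nonempty
    band sum to 1; empty bands are absent from the output.
    """
    if home is None:
        raise ValueError("mode_share_by_band requires a resolved home node")
    counts: dict[str, dict[str, int]] = {}
    for trip in trips:
        d_km = geodesic_m(home.centroid_lat, home.centroid_lon,
                          trip.destination.centroid_lat,
                          trip.destination.centroid_lon) / 1000.0
        band = cfg.band_of(d_km)
        mode = trip.main_mode
        if cfg.collapse_car and mode in ("car_driver", "car_passenger"):
            mode = "car"
        counts.setdefault(band, {})[mode] = counts.setdefault(band, {}).get(mode, 0) + 1
    shares: dict[str, dict[str, float]] = {}
    for band, by_mode in counts.items():
        n = sum(by_mode.values())
        shares[band] = {m: c / n for m, c in by_mode.items()}
    return shares


def modal_mode_by_band(shares: Mapping[str, Mapping[str, float]]) -> dict[str, str]:
    return {band: max(by_mode, key=by_mode.get) for band, by_mode in shares.items()}


def trip_complexity(per_period_mode_weights: Sequence[Mapping[str, float]],
                    cfg: ComplexityConfig = ComplexityConfig(K=10)) -> float:
    """Cross-period variability of the mode mix; shares the JSD machinery
    with node complexity."""
    return complexity(per_period_mode_weights, cfg)


def daily_mode_weights(trips_by_day: Sequence[Sequence[Trip]],
                       weighting: str = "visit_count") -> list[dict[str, float]]:
    out = []
    for trips in trips_by_day:
        w: dict[str, float] = {}
        for trip in trips:
            for leg in trip.legs:
                inc = 1.0 if weighting == "visit_count" else leg.duration_s
                w[leg.mode] = w.get(leg.mode, 0.0) + inc
        out.append(w)
    return out
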