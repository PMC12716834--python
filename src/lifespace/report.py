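"""Assemble the full per-participant life-space metrics report.

Stable output keys follow ``<family>.<metric>.<segment>``; segments are
all / day / night / weekday / weekend.  Extent metrics default to stay-node
centroids as input; complexity is reported for both visit-count and
dwell-duration weighting.
"""

from __future__ import annotations

from .core import MetricsReport, ParticipantDiary
from .geometry import (ExtentConfig, daily_path_area_km2, hull_area_km2,
                       radius_of_gyration_m)
from .nodes import (ComplexityConfig, TimeSegment, complexity,
                    daily_type_weights, node_counts, node_durations)
from .trips import (DistanceBandConfig, daily_mode_weights, mode_share_by_band,
                    trip_counts, trip_durations)

SEGMENTS = ("all", "day", "night", "weekday", "weekend")


def compute_report(diary: ParticipantDiary,
                   extent_cfg: ExtentConfig = ExtentConfig(),
                   band_cfg: DistanceBandConfig = DistanceBandConfig(),
                   include_home: bool = False) -> MetricsReport:
    """All node / trip / extent outcomes for one participant's valid days."""
    m: dict[str, float] = {}
    days = [d for d in diary.days if d.valid]
    stops = [s for d in days for s in d.stops]
    trips = [t for d in days for t in d.trips]

    for seg_name in SEGMENTS:
        seg = TimeSegment(kind=seg_name)
        nc = node_counts(stops, seg, include_home=include_home)
        nd = node_durations(stops, seg, include_home=include_home)
        m[f"node.frequency.{seg_name}"] = nc.frequency
        m[f"node.diversity.{seg_name}"] = nc.diversity
        m[f"node.duration_s.{seg_name}"] = nd.total_s
        tc = trip_counts(trips, seg)
        td = trip_durations(trips, seg)
        m[f"trip.count.{seg_name}"] = tc.trip_count
        m[f"trip.leg_count.{seg_name}"] = tc.leg_count
        m[f"trip.mode_diversity.{seg_name}"] = tc.mode_diversity
        m[f"trip.duration_s.{seg_name}"] = td.total_s
        m[f"trip.active_share.{seg_name}"] = td.active_share

    stops_by_day = [d.stops for d in days]
    trips_by_day = [d.trips for d in days]
    for weighting, tag in (("visit_count", "count"), ("dwell_duration", "dwell")):
        cfg = ComplexityConfig(weighting=weighting)
        weights = daily_type_weights(stops_by_day, cfg, include_home=include_home)
        try:
            m[f"node.complexity.{tag}"] = complexity(weights, cfg)
        except ValueError:
            pass
    mode_weights = daily_mode_weights(trips_by_day)
    try:
        m["trip.complexity.count"] = complexity(mode_weights, ComplexityConfig(K=10))
    except ValueError:
        pass

    day_areas = []
    for d in days:
        paths = [[(f.lat, f.lon) for f in leg.path]
                 for t in d.trips for leg in t.legs if len(leg.path) >= 2]
        if paths:
            day_areas.append(daily_path_area_km2(paths, extent_cfg))
    if day_areas:
        m["extent.daily_path_area_km2.mean"] = sum(day_areas) / len(day_areas)

    activity = [s for s in stops if include_home or not s.is_home]
    pts = [(s.centroid_lat, s.centroid_lon) for s in activity]
    hull_pts = pts + ([( diary.home.centroid_lat, diary.home.centroid_lon)]
                      if diary.home else [])
    if pts:
        m["extent.radius_of_gyration_m.all"] = radius_of_gyration_m(pts)
    if len(hull_pts) >= 3:
        m["extent.convex_hull_km2.all"] = hull_area_km2(hull_pts, "convex", extent_cfg).area_km2
        m["extent.concave_hull_km2.all"] = hull_area_km2(hull_pts, "concave", extent_cfg).area_km2

    if diary.home is not None and trips:
        shares = mode_share_by_band(trips, diary.home, band_cfg)
        for band, by_mode in shares.items():
            for mode, share in by_mode.items():
                m[f"trip.mode_share.{band}.{mode}"] = share

    return MetricsReport(participant_id=diary.participant_id, metrics=m)
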