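"""Fix stream -> stay nodes -> trips with mode-typed legs.

The stay-point detector is a sequential (time-ordered) scan: a maximal run of
consecutive fixes whose minimum enclosing circle has diameter <= the cluster
diameter, spanning at least the minimum dwell, becomes a candidate stop.
Sequential scanning (rather than density clustering) preserves arrival and
departure times, which every duration metric downstream needs.

Mode classification is a speed-threshold surrogate with optional rail-line
snapping; the richer multisensor inference that a production travel-diary
platform runs server-side is replaced by the diary-validation overlay, which
can override inferred node types and leg modes.
"""

from __future__ import annotations

import datetime as dt
import math
import random
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import LineString

from .core import (GpsFix, ParticipantDiary, StayNode, Trip, TripLeg,
                   ValidationError)
from .geometry import ProjectionContext, geodesic_m


@dataclass(frozen=True)
class StopDetectionConfig:
    cluster_diameter_m: float = 50.0
    min_dwell_s: float = 60.0
    max_accuracy_m: float = 100.0
    max_altitude_m: float = 300.0
    max_speed_kmh: float = 250.0
    signature_snap_m: float = 50.0

    def __post_init__(self) -> None:
        for name in ("cluster_diameter_m", "min_dwell_s", "max_accuracy_m",
                     "max_altitude_m", "max_speed_kmh", "signature_snap_m"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @property
    def cluster_radius_m(self) -> float:
        return self.cluster_diameter_m / 2.0


@dataclass(frozen=True)
class ModeHeuristicConfig:
    walk_max_kmh: float = 7.0
    bicycle_max_kmh: float = 20.0
    rail_snap_m: float = 150.0
    transfer_max_dwell_s: float = 300.0

    def __post_init__(self) -> None:
        if not 0 < self.walk_max_kmh < self.bicycle_max_kmh:
            raise ValidationError("need 0 < walk_max_kmh < bicycle_max_kmh")


@dataclass(frozen=True)
class PlaceSignature:
    """A frequently visited place with a known type (home, office, ...).

    ``transit`` marks signatures at transit infrastructure (bus stops, rail
    stations); short stops snapped to them are mode-transfer points.
    """

    signature_id: str
    lat: float
    lon: float
    node_type: str = "other"
    label: str = ""
    transit: bool = False


@dataclass
class DropRecord:
    index: int
    reason: str  # accuracy | altitude | speed


# ---------------------------------------------------------------------------
# Minimum enclosing circle (Welzl)
# ---------------------------------------------------------------------------

def min_enclosing_circle(points: Sequence[tuple[float, float]]):
    """Smallest circle containing all points: ((cx, cy), r).

    Randomized incremental (Welzl) algorithm with a deterministic shuffle.
    """
    pts = list(points)
    if not pts:
        return (0.0, 0.0), 0.0
    rng = random.Random(0x5EED)
    rng.shuffle(pts)
    c = (pts[0], 0.0)
    for i, p in enumerate(pts[1:], 1):
        if not _in_circle(c, p):
            c = _circle_with_point(pts[:i], p)
    return c


def _in_circle(circle, p, eps=1e-7) -> bool:
    (cx, cy), r = circle
    return math.hypot(p[0] - cx, p[1] - cy) <= r + eps


def _circle_with_point(pts, p):
    c = (p, 0.0)
    for i, q in enumerate(pts):
        if not _in_circle(c, q):
            c = _circle_with_two_points(pts[:i], p, q)
    return c


def _circle_with_two_points(pts, p, q):
    c = _circumcircle_2(p, q)
    for i, r in enumerate(pts):
        if not _in_circle(c, r):
            c = _circumcircle_3(p, q, r)
    return c


def _circumcircle_2(p, q):
    cx, cy = (p[0] + q[0]) / 2, (p[1] + q[1]) / 2
    return (cx, cy), math.hypot(p[0] - cx, p[1] - cy)


def _circumcircle_3(a, b, c):
    ax, ay, bx, by, cx, cy = *a, *b, *c
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if d == 0:
        # collinear: fall back to the diametral circle of the extreme pair
        pairs = [(a, b), (a, c), (b, c)]
        far = max(pairs, key=lambda pq: math.hypot(pq[0][0] - pq[1][0], pq[0][1] - pq[1][1]))
        return _circumcircle_2(*far)
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    return (ux, uy), math.hypot(ax - ux, ay - uy)


# ---------------------------------------------------------------------------
# Fix filtering
# ---------------------------------------------------------------------------

def filter_fixes(fixes: Sequence[GpsFix],
                 cfg: StopDetectionConfig = StopDetectionConfig()
                 ) -> tuple[list[GpsFix], list[DropRecord]]:
    """Drop implausible fixes: poor accuracy, impossible altitude, or an
    implied speed from the previous *kept* fix beyond the speed ceiling."""
    kept: list[GpsFix] = []
    drops: list[DropRecord] = []
    for i, fix in enumerate(fixes):
        if fix.accuracy_m is not None and fix.accuracy_m > cfg.max_accuracy_m:
            drops.append(DropRecord(i, "accuracy"))
            continue
        if fix.altitude_m is not None and fix.altitude_m > cfg.max_altitude_m:
            drops.append(DropRecord(i, "altitude"))
            continue
        if kept:
            prev = kept[-1]
            dt_s = (fix.t - prev.t).total_seconds()
            if dt_s > 0:
                speed_kmh = geodesic_m(prev.lat, prev.lon, fix.lat, fix.lon) / dt_s * 3.6
                if speed_kmh > cfg.max_speed_kmh:
                    drops.append(DropRecord(i, "speed"))
                    continue
        kept.append(fix)
    return kept, drops


# ---------------------------------------------------------------------------
# Stay-point detection
# ---------------------------------------------------------------------------

def detect_stops(fixes: Sequence[GpsFix],
                 cfg: StopDetectionConfig = StopDetectionConfig(),
                 signatures: Sequence[PlaceSignature] = (),
                 ) -> list[StayNode]:
    """Detect stay nodes by sequential scan.

    From each start index the window grows while the minimum enclosing circle
    of the member fixes stays within the cluster diameter (enclosure is
    monotone, so greedy extension finds the maximal window).  Windows
    spanning at least min_dwell_s become stops; the scan resumes after the
    window.  Candidates are snapped to nearby place signatures, then
    adjacent stops separated only by fixes near their joint location are
    merged (GPS jitter can split a single true stay).
    """
    if not fixes:
        return []
    ctx = ProjectionContext.for_points([f.lat for f in fixes], [f.lon for f in fixes])
    xs, ys = ctx.project([f.lat for f in fixes], [f.lon for f in fixes])
    pts = list(zip(np.atleast_1d(xs).tolist(), np.atleast_1d(ys).tolist()))

    raw: list[tuple[int, int]] = []  # inclusive index windows
    n = len(fixes)
    i = 0
    while i < n:
        # grow the window incrementally: enclosure is monotone in j, so the
        # first failure marks the maximal window for this start
        j = i
        circle = (pts[i], 0.0)
        while j + 1 < n:
            p = pts[j + 1]
            cand = circle if _in_circle(circle, p) else \
                _circle_with_point(pts[i:j + 1], p)
            if 2 * cand[1] > cfg.cluster_diameter_m:
                break
            circle = cand
            j += 1
        if (fixes[j].t - fixes[i].t).total_seconds() >= cfg.min_dwell_s:
            raw.append((i, j))
            i = j + 1
        else:
            i += 1

    merged = _merge_windows(raw, pts, fixes, cfg)
    stops = []
    for k, (a, b) in enumerate(merged):
        stop = _window_to_stop(fixes, a, b, k)
        stops.append(_snap_to_signature(stop, signatures, cfg))
    stops = _merge_same_signature(stops)
    return stops


def _merge_windows(windows, pts, fixes, cfg):
    """Merge adjacent windows whose gap fixes all lie within the cluster
    radius of the midpoint of the two window centroids."""
    if not windows:
        return []
    out = [windows[0]]
    for a, b in windows[1:]:
        pa, pb = out[-1]
        ca = np.mean(np.asarray(pts[pa:pb + 1]), axis=0)
        cb = np.mean(np.asarray(pts[a:b + 1]), axis=0)
        mid = (ca + cb) / 2
        gap = pts[pb + 1:a]
        near = (math.hypot(*(ca - cb)) <= cfg.cluster_diameter_m and
                all(math.hypot(p[0] - mid[0], p[1] - mid[1]) <= cfg.cluster_radius_m
                    for p in gap))
        if near:
            out[-1] = (pa, b)
        else:
            out.append((a, b))
    return out


def _window_to_stop(fixes, a, b, k) -> StayNode:
    lat = float(np.mean([f.lat for f in fixes[a:b + 1]]))
    lon = float(np.mean([f.lon for f in fixes[a:b + 1]]))
    return StayNode(node_id=f"stop{k}", centroid_lat=lat, centroid_lon=lon,
                    arrive_t=fixes[a].t, depart_t=fixes[b].t)


def _snap_to_signature(stop: StayNode, signatures, cfg: StopDetectionConfig) -> StayNode:
    best, best_d = None, math.inf
    for sig in signatures:
        d = geodesic_m(stop.centroid_lat, stop.centroid_lon, sig.lat, sig.lon)
        if d <= cfg.signature_snap_m and d < best_d:
            best, best_d = sig, d
    if best is None:
        return stop
    return StayNode(node_id=stop.node_id, centroid_lat=best.lat, centroid_lon=best.lon,
                    arrive_t=stop.arrive_t, depart_t=stop.depart_t,
                    node_type=best.node_type, signature_id=best.signature_id,
                    is_home=(best.node_type == "home"))


def _merge_same_signature(stops: list[StayNode]) -> list[StayNode]:
    """Adjacent stops snapped to one signature are a single stay split by noise."""
    out: list[StayNode] = []
    for stop in stops:
        if (out and stop.signature_id is not None
                and out[-1].signature_id == stop.signature_id):
            prev = out[-1]
            out[-1] = StayNode(node_id=prev.node_id, centroid_lat=prev.centroid_lat,
                               centroid_lon=prev.centroid_lon, arrive_t=prev.arrive_t,
                               depart_t=stop.depart_t, node_type=prev.node_type,
                               signature_id=prev.signature_id, is_home=prev.is_home)
        else:
            out.append(stop)
    return out


# ---------------------------------------------------------------------------
# Trip segmentation and mode classification
# ---------------------------------------------------------------------------

def classify_mode(path: Sequence[GpsFix],
                  cfg: ModeHeuristicConfig = ModeHeuristicConfig(),
                  rail_lines: Sequence[Sequence[tuple[float, float]]] = (),
                  ) -> str:
    """Speed-threshold mode surrogate.

    Median inter-fix speed below walk_max -> walk; below bicycle_max ->
    bicycle; otherwise motorized.  A motorized leg with >=80% of fixes within
    rail_snap_m of a rail polyline is typed train; bus vs car resolution is
    left to the diary-validation overlay.
    """
    if len(path) < 2:
        return "other"
    speeds = []
    for a, b in zip(path, path[1:]):
        dt_s = (b.t - a.t).total_seconds()
        if dt_s > 0:
            speeds.append(geodesic_m(a.lat, a.lon, b.lat, b.lon) / dt_s * 3.6)
    if not speeds:
        return "other"
    med = float(np.median(speeds))
    if med < cfg.walk_max_kmh:
        return "walk"
    if med < cfg.bicycle_max_kmh:
        return "bicycle"
    if rail_lines and _rail_fraction(path, rail_lines, cfg) >= 0.8:
        return "train"
    return "motorized_unspecified"


def _rail_fraction(path, rail_lines, cfg: ModeHeuristicConfig) -> float:
    lats = [f.lat for f in path]
    lons = [f.lon for f in path]
    all_lats = lats + [p[0] for line in rail_lines for p in line]
    all_lons = lons + [p[1] for line in rail_lines for p in line]
    ctx = ProjectionContext.for_points(all_lats, all_lons)
    lines = []
    for line in rail_lines:
        x, y = ctx.project([p[0] for p in line], [p[1] for p in line])
        lines.append(LineString(list(zip(np.atleast_1d(x), np.atleast_1d(y)))))
    x, y = ctx.project(lats, lons)
    near = 0
    for px, py in zip(np.atleast_1d(x), np.atleast_1d(y)):
        from shapely.geometry import Point
        if min(line.distance(Point(px, py)) for line in lines) <= cfg.rail_snap_m:
            near += 1
    return near / len(path)


#: Below this many fixes a segment's median-speed mode is unreliable
#: (too few inter-fix speeds to vote on).
MIN_MODE_FIXES = 10


def segment_trips(fixes: Sequence[GpsFix], stops: Sequence[StayNode],
                  mode_cfg: ModeHeuristicConfig = ModeHeuristicConfig(),
                  rail_lines: Sequence[Sequence[tuple[float, float]]] = (),
                  signatures: Sequence[PlaceSignature] = (),
                  ) -> list[Trip]:
    """Build trips between consecutive *activity* stops.

    Interior stops with dwell below transfer_max_dwell_s are transfer
    candidates: they split the movement into candidate segments.  A leg is
    a maximal run of one transport mode, so adjacent same-mode segments are
    re-joined.  Across a candidate stop that is not a known transit
    signature, a boundary additionally requires a *reliable* mode change:
    when either side is too short to classify confidently, the combined
    path is classified and absorbs the short side if it agrees with the
    longer one (short GPS lingering mid-walk is not a transfer).  Each leg
    gets a geodesic endpoint distance (linear_m) and a summed along-path
    distance (path_m).
    """
    stops = sorted(stops, key=lambda s: s.arrive_t)
    for a, b in zip(stops, stops[1:]):
        if b.arrive_t < a.depart_t:
            raise ValidationError(f"stops {a.node_id} and {b.node_id} overlap in time")

    transit_ids = {s.signature_id for s in signatures if s.transit}
    activity = [s for s in stops if s.dwell_s >= mode_cfg.transfer_max_dwell_s]
    transfers = [s for s in stops if s.dwell_s < mode_cfg.transfer_max_dwell_s]

    def path_of(t0, t1):
        return tuple(f for f in fixes if t0 <= f.t <= t1)

    trips: list[Trip] = []
    for origin, dest in zip(activity, activity[1:]):
        interior = [s for s in transfers
                    if origin.depart_t <= s.arrive_t and s.depart_t <= dest.arrive_t]
        # candidate segments split at every interior short stop
        segments: list[list] = []  # [start_t, end_t, mode, n_fixes, sep_stop]
        cursor = origin.depart_t
        sep = None
        for stop in interior + [dest]:
            start_t, end_t = cursor, stop.arrive_t
            cursor = stop.depart_t
            if end_t <= start_t:
                sep = stop
                continue
            path = path_of(start_t, end_t)
            segments.append([start_t, end_t,
                             classify_mode(path, mode_cfg, rail_lines),
                             len(path), sep])
            sep = stop

        merged: list[list] = []
        for seg in segments:
            if merged:
                prev = merged[-1]
                at_transit = (seg[4] is not None
                              and seg[4].signature_id in transit_ids)
                join = prev[2] == seg[2]
                if not join and not at_transit and min(prev[3], seg[3]) < MIN_MODE_FIXES:
                    combined = classify_mode(path_of(prev[0], seg[1]),
                                             mode_cfg, rail_lines)
                    if combined in (prev[2], seg[2]):
                        join = True
                        prev[2] = combined
                if join:
                    prev[1] = seg[1]
                    prev[3] += seg[3]
                    continue
            merged.append(seg)

        legs = []
        for start_t, end_t, mode, _, _ in merged:
            legs.append(_make_leg(start_t, end_t, mode, path_of(start_t, end_t),
                                  fallback=(origin, dest)))
        if legs:
            trips.append(Trip(origin=origin, destination=dest, legs=tuple(legs)))
    return trips


def _make_leg(start_t, end_t, mode, path, fallback) -> TripLeg:
    if len(path) >= 2:
        o, d = path[0], path[-1]
        linear = geodesic_m(o.lat, o.lon, d.lat, d.lon)
        path_m = sum(geodesic_m(a.lat, a.lon, b.lat, b.lon)
                     for a, b in zip(path, path[1:]))
    else:
        o, d = fallback
        linear = geodesic_m(o.centroid_lat, o.centroid_lon,
                            d.centroid_lat, d.centroid_lon)
        path_m = linear
    return TripLeg(start_t=start_t, end_t=end_t, mode=mode, path=path,
                   linear_m=linear, path_m=max(path_m, linear - TripLeg._NOISE_EPS_M))


# ---------------------------------------------------------------------------
# Compliance monitoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplianceAlert:
    start_day_index: int
    length_days: int


def flag_compliance_gaps(diary: ParticipantDiary, min_run: int = 3) -> list[ComplianceAlert]:
    """One alert per maximal run of >= min_run consecutive days with no usable
    data (no_data or no_device); mirrors field check-in practice."""
    alerts = []
    run_start = None
    for i, day in enumerate(diary.days):
        gap = (not day.valid) and day.invalid_reason in ("no_data", "no_device")
        if gap and run_start is None:
            run_start = i
        elif not gap and run_start is not None:
            if i - run_start >= min_run:
                alerts.append(ComplianceAlert(run_start, i - run_start))
            run_start = None
    if run_start is not None and len(diary.days) - run_start >= min_run:
        alerts.append(ComplianceAlert(run_start, len(diary.days) - run_start))
    return alerts
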