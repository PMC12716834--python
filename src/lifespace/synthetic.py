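"""Seeded generator of ground-truth 14-day diaries and noisy sensor streams.

The generator emulates the structure of a smartphone travel-diary dataset
for a home-anchored urban cohort: every day starts and ends at home (always
covering the 03:00 overnight instant), activity visits are drawn from a
14-type node taxonomy around the home, trips shorter than a tolerable
walking distance (2 km) are walked while longer ones become three-leg
walk - bus - walk journeys with short transfer stops, GPS fixes are sampled
on a fixed interval with isotropic Gaussian noise and indoor dropout, and
participants living above ground produce barometric ramps on every home
entry and exit.

Ground-truth metric values are computed directly from the schedule — an
independent path from the detection pipeline — so pipeline tests are true
oracle comparisons.  All randomness flows from the single scenario seed.
Cohort strata (age bracket 40:60, housing 20:80, frailty 30:70) are matched
exactly by largest-remainder allocation whenever n divides the ratios.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import LOCAL_TZ, GpsFix
from .geometry import (ProjectionContext, hull_area_km2,
                       radius_of_gyration_m)
from .pipeline import PlaceSignature

BASE_PRESSURE_HPA = 1013.0
METERS_PER_HPA = 8.43
FLOOR_HEIGHT_M = 3.0


@dataclass(frozen=True)
class PlaceSpec:
    """A typed place at a fixed local offset (meters east/north of home)."""

    name: str
    node_type: str
    dx_m: float
    dy_m: float

    @property
    def dist_m(self) -> float:
        return math.hypot(self.dx_m, self.dy_m)


def default_places() -> tuple[PlaceSpec, ...]:
    """A small abstract city: near amenities walkable, far ones transit-served."""
    return (
        PlaceSpec("wet_market", "market", 350.0, 200.0),
        PlaceSpec("hawker_centre", "dining", -500.0, 300.0),
        PlaceSpec("corner_errand", "errand", 150.0, -450.0),
        PlaceSpec("park", "exercise", -300.0, -700.0),
        PlaceSpec("void_deck_social", "social", 600.0, 900.0),
        PlaceSpec("temple", "religious", 900.0, -1100.0),
        PlaceSpec("mall", "shopping", 3500.0, 2200.0),
        PlaceSpec("polyclinic", "healthcare", -2800.0, 1500.0),
        PlaceSpec("community_club", "recreation", 4200.0, -2600.0),
    )


DEFAULT_VISIT_INTENSITY = {
    "dining": 0.6, "market": 0.35, "errand": 0.25, "exercise": 0.35,
    "social": 0.2, "religious": 0.1, "shopping": 0.3, "healthcare": 0.08,
    "recreation": 0.12,
}


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int = 0
    n_participants: int = 1
    days: int = 14
    start_date: dt.date = dt.date(2025, 3, 3)  # a Monday
    home_lat: float = 1.35
    home_lon: float = 103.85
    places: tuple[PlaceSpec, ...] = field(default_factory=default_places)
    visit_intensity: dict = field(default_factory=lambda: dict(DEFAULT_VISIT_INTENSITY))
    walk_threshold_km: float = 2.0
    walk_speed_kmh: float = 4.8
    bus_speed_kmh: float = 30.0
    activity_dwell_s: tuple[float, float] = (1800.0, 7200.0)
    transfer_dwell_s: float = 180.0
    bus_stop_offset_m: float = 200.0
    gps_noise_sigma_m: float = 10.0
    sample_interval_s: float = 30.0
    indoor_dropout_prob: float = 0.1
    baro_interval_s: float = 10.0
    baro_ramp_s: float = 40.0
    max_floor: int = 20
    quota_age: tuple[int, int] = (40, 60)       # younger-old : older-old
    quota_housing: tuple[int, int] = (20, 80)   # private : public
    quota_frailty: tuple[int, int] = (30, 70)   # prefrail/frail : robust

    def __post_init__(self) -> None:
        if not 0.0 <= self.indoor_dropout_prob <= 1.0:
            raise ValueError("indoor_dropout_prob must be in [0, 1]")
        if any(v < 0 for v in self.visit_intensity.values()):
            raise ValueError("visit intensities must be >= 0")


@dataclass
class TrueStay:
    lat: float
    lon: float
    t0: dt.datetime
    t1: dt.datetime
    node_type: str
    place_name: str
    is_home: bool = False
    is_transfer: bool = False
    indoor: bool = True


@dataclass
class TrueLeg:
    mode: str
    t0: dt.datetime
    t1: dt.datetime
    polyline_xy: list[tuple[float, float]]  # local meters (projection at home)


@dataclass
class TrueTrip:
    origin_name: str
    dest_name: str
    legs: list[TrueLeg]


@dataclass
class TrueVerticalEvent:
    t: dt.datetime
    floors_delta: int


@dataclass
class GroundTruth:
    participant_id: str
    participant_index: int
    home: tuple[float, float]
    floor: int
    strata: dict
    start_date: dt.date
    days: int
    stays: list[TrueStay]
    trips: list[TrueTrip]
    vertical_events: list[TrueVerticalEvent]
    true_metrics: dict

    @property
    def activity_stays(self) -> list[TrueStay]:
        return [s for s in self.stays if not s.is_home and not s.is_transfer]

    @property
    def home_stays(self) -> list[TrueStay]:
        return [s for s in self.stays if s.is_home]

    def projection(self) -> ProjectionContext:
        return ProjectionContext(self.home[0], self.home[1])


# ---------------------------------------------------------------------------
# Cohort / schedule generation
# ---------------------------------------------------------------------------

def _quota_labels(n: int, ratio: tuple[int, int], labels: tuple[str, str],
                  rng: np.random.Generator) -> list[str]:
    """Exact largest-remainder split of n into two strata, order shuffled."""
    share = ratio[0] / (ratio[0] + ratio[1])
    n_first = round(n * share)
    out = [labels[0]] * n_first + [labels[1]] * (n - n_first)
    rng.shuffle(out)
    return out


def generate_cohort(cfg: ScenarioConfig) -> list[GroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    age = _quota_labels(n, cfg.quota_age, ("50-62", "63+"), rng)
    housing = _quota_labels(n, cfg.quota_housing, ("private", "public"), rng)
    frailty = _quota_labels(n, cfg.quota_frailty, ("prefrail_frail", "robust"), rng)
    return [
        generate_diary(cfg, participant_index=i,
                       strata={"age_bracket": age[i], "housing": housing[i],
                               "frailty": frailty[i]})
        for i in range(n)
    ]


def generate_diary(cfg: ScenarioConfig, participant_index: int = 0,
                   strata: dict | None = None) -> GroundTruth:
    """Build one participant's ground-truth schedule, deterministically
    from (cfg.seed, participant_index)."""
    rng = np.random.default_rng([cfg.seed, participant_index])
    if strata is None:
        strata = {"age_bracket": "63+", "housing": "public", "frailty": "robust"}

    # spread homes on a coarse grid so participants do not overlap
    home_lat = cfg.home_lat + 0.02 * (participant_index % 7)
    home_lon = cfg.home_lon + 0.02 * (participant_index // 7)
    ctx = ProjectionContext(home_lat, home_lon)
    floor = int(rng.integers(1, cfg.max_floor + 1)) if strata["housing"] == "public" \
        else int(rng.integers(0, 4))

    def to_latlon(dx: float, dy: float) -> tuple[float, float]:
        lat, lon = ctx.inverse(dx, dy)
        return float(lat), float(lon)

    home = to_latlon(0.0, 0.0)
    by_type: dict[str, list[PlaceSpec]] = {}
    for p in cfg.places:
        by_type.setdefault(p.node_type, []).append(p)

    stays: list[TrueStay] = []
    trips: list[TrueTrip] = []
    vertical: list[TrueVerticalEvent] = []

    day0 = dt.datetime.combine(cfg.start_date, dt.time(0), tzinfo=LOCAL_TZ)
    home_since = day0

    def close_home_stay(until: dt.datetime) -> None:
        nonlocal home_since
        if until > home_since:
            stays.append(TrueStay(home[0], home[1], home_since, until,
                                  "home", "home", is_home=True))

    def emit_trip(cursor: dt.datetime, leg_plan) -> tuple[dt.datetime, list[TrueLeg]]:
        legs: list[TrueLeg] = []
        for k, (mode, pts, dur) in enumerate(leg_plan):
            t1 = cursor + dt.timedelta(seconds=dur)
            legs.append(TrueLeg(mode=mode, t0=cursor, t1=t1, polyline_xy=pts))
            cursor = t1
            if k < len(leg_plan) - 1:
                t_end = cursor + dt.timedelta(seconds=cfg.transfer_dwell_s)
                slat, slon = to_latlon(*pts[-1])
                stays.append(TrueStay(slat, slon, cursor, t_end, "other",
                                      f"transfer_at_{pts[-1][0]:.0f}_{pts[-1][1]:.0f}",
                                      is_transfer=True, indoor=False))
                cursor = t_end
        return cursor, legs

    for d in range(cfg.days):
        day_start = day0 + dt.timedelta(days=d)
        cursor = day_start + dt.timedelta(hours=8, minutes=int(rng.integers(0, 60)))
        if cursor < home_since:
            cursor = home_since
        latest_return = day_start + dt.timedelta(hours=21)

        outings: list[PlaceSpec] = []
        for node_type, rate in cfg.visit_intensity.items():
            k = int(rng.poisson(rate))
            for _ in range(min(k, 2)):
                options = by_type.get(node_type)
                if options:
                    outings.append(options[int(rng.integers(0, len(options)))])
        rng.shuffle(outings)

        for place in outings:
            dwell = float(rng.uniform(*cfg.activity_dwell_s))
            out_plan = _route_legs(cfg, place, outbound=True)
            back_plan = _route_legs(cfg, place, outbound=False)
            t_travel = sum(l[2] for l in out_plan) + sum(l[2] for l in back_plan)
            t_transfer = cfg.transfer_dwell_s * (max(len(out_plan) - 1, 0)
                                                 + max(len(back_plan) - 1, 0))
            if cursor + dt.timedelta(seconds=t_travel + t_transfer + dwell) > latest_return:
                continue

            close_home_stay(cursor)
            if floor > 0:
                vertical.append(TrueVerticalEvent(cursor, -floor))

            cursor, legs_out = emit_trip(cursor, out_plan)
            trips.append(TrueTrip("home", place.name, legs_out))
            arrive = cursor
            cursor = arrive + dt.timedelta(seconds=dwell)
            plat, plon = to_latlon(place.dx_m, place.dy_m)
            stays.append(TrueStay(plat, plon, arrive, cursor,
                                  place.node_type, place.name))

            cursor, legs_back = emit_trip(cursor, back_plan)
            trips.append(TrueTrip(place.name, "home", legs_back))
            home_since = cursor
            if floor > 0:
                vertical.append(TrueVerticalEvent(cursor, floor))
            cursor += dt.timedelta(minutes=float(rng.uniform(20, 60)))

    close_home_stay(day0 + dt.timedelta(days=cfg.days))
    stays.sort(key=lambda s: s.t0)

    gt = GroundTruth(
        participant_id=f"p{participant_index:03d}",
        participant_index=participant_index,
        home=home, floor=floor, strata=strata,
        start_date=cfg.start_date, days=cfg.days,
        stays=stays, trips=trips, vertical_events=vertical,
        true_metrics={},
    )
    gt.true_metrics = _true_metrics(gt)
    return gt


def _route_legs(cfg: ScenarioConfig, place: PlaceSpec, outbound: bool):
    """Leg plan as (mode, [(dx,dy)...], duration_s) tuples in travel order."""
    home_xy = (0.0, 0.0)
    place_xy = (place.dx_m, place.dy_m)
    walk_speed = cfg.walk_speed_kmh / 3.6
    if place.dist_m < cfg.walk_threshold_km * 1000.0:
        dur = place.dist_m / walk_speed
        pts = [home_xy, place_xy] if outbound else [place_xy, home_xy]
        return [("walk", pts, dur)]
    home_stop = (cfg.bus_stop_offset_m, 50.0)
    frac = (place.dist_m - cfg.bus_stop_offset_m) / place.dist_m
    place_stop = (place.dx_m * frac, place.dy_m * frac)
    bus_speed = cfg.bus_speed_kmh / 3.6
    d1 = math.hypot(*home_stop)
    d2 = math.hypot(place_stop[0] - home_stop[0], place_stop[1] - home_stop[1])
    d3 = math.hypot(place_xy[0] - place_stop[0], place_xy[1] - place_stop[1])
    legs = [("walk", [home_xy, home_stop], d1 / walk_speed),
            ("bus", [home_stop, place_stop], d2 / bus_speed),
            ("walk", [place_stop, place_xy], d3 / walk_speed)]
    if not outbound:
        legs = [(m, list(reversed(p)), s) for m, p, s in reversed(legs)]
    return legs


def _true_metrics(gt: GroundTruth) -> dict:
    acts = gt.activity_stays
    pts = [(s.lat, s.lon) for s in acts]
    metrics = {
        "n_activity_stops": len(acts),
        "n_trips": len(gt.trips),
        "n_legs": sum(len(t.legs) for t in gt.trips),
        "node_diversity": len({s.node_type for s in acts}),
        "total_floors_up": sum(e.floors_delta for e in gt.vertical_events
                               if e.floors_delta > 0),
        "total_floors_down": -sum(e.floors_delta for e in gt.vertical_events
                                  if e.floors_delta < 0),
    }
    if pts:
        metrics["rg_m"] = radius_of_gyration_m(pts)
        metrics["convex_hull_km2"] = hull_area_km2(pts + [gt.home]).area_km2
    return metrics


# ---------------------------------------------------------------------------
# Sensor rendering
# ---------------------------------------------------------------------------

def render_fixes(gt: GroundTruth, cfg: ScenarioConfig) -> list[GpsFix]:
    """Sample noisy GPS fixes along the ground-truth timeline.

    Positions are taken every sample_interval_s (stay position, or linear
    interpolation along the leg polyline), perturbed by isotropic Gaussian
    noise of sigma gps_noise_sigma_m; samples during indoor stays are
    dropped with indoor_dropout_prob.  Deterministic per (seed, participant).
    """
    rng = np.random.default_rng([cfg.seed, gt.participant_index, 1])
    ctx = gt.projection()
    segments: list[tuple[str, dt.datetime, dt.datetime, object]] = []
    for s in gt.stays:
        segments.append(("stay", s.t0, s.t1, s))
    for trip in gt.trips:
        for leg in trip.legs:
            segments.append(("leg", leg.t0, leg.t1, leg))
    segments.sort(key=lambda e: e[1])

    fixes: list[GpsFix] = []
    interval = dt.timedelta(seconds=cfg.sample_interval_s)
    for kind, t0, t1, payload in segments:
        t = t0
        while t < t1:
            if kind == "stay":
                stay = payload
                if stay.indoor and rng.random() < cfg.indoor_dropout_prob:
                    t += interval
                    continue
                x, y = ctx.project(stay.lat, stay.lon)
                x, y = float(x), float(y)
            else:
                leg = payload
                frac = (t - leg.t0).total_seconds() / max(
                    (leg.t1 - leg.t0).total_seconds(), 1e-9)
                x, y = _interp_polyline(leg.polyline_xy, frac)
            nx = x + rng.normal(0.0, cfg.gps_noise_sigma_m)
            ny = y + rng.normal(0.0, cfg.gps_noise_sigma_m)
            lat, lon = ctx.inverse(nx, ny)
            fixes.append(GpsFix(participant_id=gt.participant_id, t=t,
                                lat=float(lat), lon=float(lon),
                                accuracy_m=cfg.gps_noise_sigma_m))
            t += interval
    fixes.sort(key=lambda f: f.t)
    return fixes


def _interp_polyline(pts: Sequence[tuple[float, float]], frac: float
                     ) -> tuple[float, float]:
    frac = min(max(frac, 0.0), 1.0)
    seg_len = [math.hypot(b[0] - a[0], b[1] - a[1]) for a, b in zip(pts, pts[1:])]
    total = sum(seg_len)
    if total == 0:
        return pts[0]
    target = frac * total
    acc = 0.0
    for (a, b), L in zip(zip(pts, pts[1:]), seg_len):
        if acc + L >= target and L > 0:
            f = (target - acc) / L
            return a[0] + f * (b[0] - a[0]), a[1] + f * (b[1] - a[1])
        acc += L
    return pts[-1]


def render_barometer(gt: GroundTruth, cfg: ScenarioConfig
                     ) -> list[tuple[dt.datetime, float]]:
    """Pressure trace: slow diurnal drift minus elevation / (8.43 m per hPa).

    The elevation profile follows the home stays: an up-ramp of baro_ramp_s
    at every home arrival and a down-ramp ending at every departure (skipped
    at the very start and end of the tracking window, where no transition
    happened).  A ground-floor home yields drift only.
    """
    t0 = dt.datetime.combine(gt.start_date, dt.time(0), tzinfo=LOCAL_TZ)
    n = int(gt.days * 86400 / cfg.baro_interval_s) + 1
    ts = np.arange(n) * cfg.baro_interval_s
    drift = 0.3 * np.sin(2 * math.pi * ts / 86400.0)
    elev = np.zeros(n)
    if gt.floor > 0:
        floor_h = gt.floor * FLOOR_HEIGHT_M
        # lift ride duration ~ 1.5 m/s, at least one sample interval
        ramp_s = min(max(floor_h / 1.5, cfg.baro_interval_s), 60.0)
        ramp = max(int(round(ramp_s / cfg.baro_interval_s)), 1)
        for s in gt.home_stays:
            i0 = int((s.t0 - t0).total_seconds() / cfg.baro_interval_s)
            i1 = int((s.t1 - t0).total_seconds() / cfg.baro_interval_s)
            up_end = i0 if i0 <= 0 else min(i0 + ramp, n)
            down_start = i1 if i1 >= n - 1 else max(i1 - ramp, 0)
            elev[max(up_end, 0):min(down_start + 1, n)] = floor_h
            if i0 > 0:
                for k in range(ramp):
                    idx = i0 + k
                    if 0 <= idx < n:
                        elev[idx] = max(elev[idx], floor_h * k / ramp)
            if i1 < n - 1:
                for k in range(ramp + 1):
                    idx = i1 - k
                    if 0 <= idx < n:
                        elev[idx] = max(elev[idx], floor_h * k / ramp)
    pressure = BASE_PRESSURE_HPA + drift - elev / METERS_PER_HPA
    times = [t0 + dt.timedelta(seconds=float(s)) for s in ts]
    return list(zip(times, pressure.tolist()))


# ---------------------------------------------------------------------------
# Signatures for the pipeline
# ---------------------------------------------------------------------------

def signatures_for(gt: GroundTruth, cfg: ScenarioConfig) -> list[PlaceSignature]:
    """Place signatures (home, catalog places, transfer bus stops) matching
    the ground-truth city: the pipeline's validated-place overlay."""
    ctx = gt.projection()
    sigs = [PlaceSignature("home", gt.home[0], gt.home[1], "home", "home")]
    for p in cfg.places:
        lat, lon = ctx.inverse(p.dx_m, p.dy_m)
        sigs.append(PlaceSignature(p.name, float(lat), float(lon), p.node_type, p.name))
    seen: set[str] = set()
    for s in gt.stays:
        if s.is_transfer and s.place_name not in seen:
            seen.add(s.place_name)
            sigs.append(PlaceSignature(s.place_name, s.lat, s.lon, "other",
                                       "bus_stop", transit=True))
    return sigs


# ---------------------------------------------------------------------------
# Canonical worked example: a three-leg journey to a shopping centre
# ---------------------------------------------------------------------------

def walk_bus_walk_example(seed: int = 0, noise_sigma_m: float = 10.0,
                          sample_interval_s: float = 30.0):
    """Fix stream for the classic three-leg journey: walk from home to a bus
    stop, a bus ride, and a final walk to a shopping centre, with two short
    (sub-5-minute) transfer stops at the bus stops.

    Returns ``(fixes, signatures)`` ready for stop detection and trip
    segmentation; the correct segmentation is exactly 1 trip of 3 legs.
    """
    rng = np.random.default_rng(seed)
    home = (1.35, 103.85)
    ctx = ProjectionContext(*home)
    stop_a = (250.0, 0.0)          # bus stop near home, 250 m walk
    stop_b = (4250.0, 0.0)         # bus stop near the mall, 4 km ride
    mall = (4500.0, 0.0)           # 250 m final walk

    t = dt.datetime(2025, 3, 8, 10, 0, tzinfo=LOCAL_TZ)
    segments = [  # (kind, xy_from, xy_to, duration_s)
        ("stay", (0.0, 0.0), (0.0, 0.0), 600.0),        # at home
        ("move", (0.0, 0.0), stop_a, 300.0),            # walk ~3 km/h
        ("stay", stop_a, stop_a, 180.0),                # transfer < 5 min
        ("move", stop_a, stop_b, 600.0),                # bus 24 km/h
        ("stay", stop_b, stop_b, 180.0),                # transfer < 5 min
        ("move", stop_b, mall, 300.0),                  # walk
        ("stay", mall, mall, 900.0),                    # shopping
    ]
    fixes: list[GpsFix] = []
    for kind, a, b, dur in segments:
        t_end = t + dt.timedelta(seconds=dur)
        cur = t
        while cur < t_end:
            frac = (cur - t).total_seconds() / dur
            x = a[0] + frac * (b[0] - a[0]) + rng.normal(0, noise_sigma_m)
            y = a[1] + frac * (b[1] - a[1]) + rng.normal(0, noise_sigma_m)
            lat, lon = ctx.inverse(x, y)
            fixes.append(GpsFix(participant_id="wx", t=cur,
                                lat=float(lat), lon=float(lon),
                                accuracy_m=noise_sigma_m))
            cur += dt.timedelta(seconds=sample_interval_s)
        t = t_end

    def sig(sid, xy, node_type, transit=False):
        lat, lon = ctx.inverse(*xy)
        return PlaceSignature(sid, float(lat), float(lon), node_type,
                              sid, transit=transit)

    signatures = [sig("home", (0.0, 0.0), "home"),
                  sig("bus_stop_a", stop_a, "other", transit=True),
                  sig("bus_stop_b", stop_b, "other", transit=True),
                  sig("mall", mall, "shopping")]
    return fixes, signatures
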