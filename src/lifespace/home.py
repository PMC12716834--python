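"""Home-node inference, self-declared/GPS reconciliation, and vertical
life space from barometric traces.

The GPS home node (GPN) is the stay node occupied at the overnight instant
(03:00 local by default) on the plurality of observed nights.  It is
reconciled against the geocoded self-declared address (SDN) with a 100-m
rule: the SDN wins either way, but deviations beyond the threshold raise a
review flag for manual inspection.

Vertical trips are detected from rapid pressure excursions while the phone
is horizontally still near home; height uses the sea-level linearization
(~8.43 m per hPa), accurate to within ~1% at residential tower heights.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Sequence

from .core import LOCAL_TZ, GpsFix, ParticipantDiary, StayNode
from .geometry import geodesic_m


@dataclass(frozen=True)
class HomeConfig:
    overnight_time: dt.time = dt.time(3, 0)
    snap_threshold_m: float = 100.0
    min_nights: int = 7

    def __post_init__(self) -> None:
        if self.snap_threshold_m <= 0:
            raise ValueError("snap_threshold_m must be positive")
        if not 1 <= self.min_nights <= 14:
            raise ValueError("min_nights must be in 1..14")


@dataclass(frozen=True)
class BaroConfig:
    meters_per_hpa: float = 8.43
    floor_height_m: float = 3.0
    min_rate_hpa_per_10s: float = 0.1
    horizontal_still_radius_m: float = 30.0

    def __post_init__(self) -> None:
        for name in ("meters_per_hpa", "floor_height_m",
                     "min_rate_hpa_per_10s", "horizontal_still_radius_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class HomeInference:
    gpn: tuple[float, float] | None
    nights_observed: int
    modal_share: float
    tie: bool = False


@dataclass
class HomeDecision:
    home: tuple[float, float]
    source: str  # "SDN" | "GPN"
    review_flag: bool
    deviation_m: float | None
    missing_gpn: bool = False
    missing_sdn: bool = False


@dataclass
class VerticalEvent:
    t: dt.datetime
    floors_delta: int
    delta_hpa: float


@dataclass
class VerticalResult:
    events: list[VerticalEvent]
    total_floors_up: int
    total_floors_down: int
    has_pressure: bool = True


def infer_home(diary: ParticipantDiary, cfg: HomeConfig = HomeConfig()) -> HomeInference:
    """GPS home node from overnight stays.

    For each diary date, the stay node covering the overnight instant is the
    night's anchor.  Anchors within the snap threshold of each other are one
    candidate home; the plurality candidate wins, ties broken by larger
    total overnight dwell (flagged).  Unresolved below min_nights.
    """
    anchors: list[StayNode] = []
    for day in diary.days:
        instant = dt.datetime.combine(day.date, cfg.overnight_time, tzinfo=LOCAL_TZ)
        for stop in day.stops:
            if stop.arrive_t <= instant < stop.depart_t:
                anchors.append(stop)
                break
    nights = len(anchors)
    if nights < cfg.min_nights:
        return HomeInference(gpn=None, nights_observed=nights, modal_share=0.0)

    # cluster anchors by proximity (single-link within snap threshold)
    clusters: list[list[StayNode]] = []
    for a in anchors:
        placed = False
        for cl in clusters:
            if any(geodesic_m(a.centroid_lat, a.centroid_lon,
                              b.centroid_lat, b.centroid_lon) <= cfg.snap_threshold_m
                   for b in cl):
                cl.append(a)
                placed = True
                break
        if not placed:
            clusters.append([a])

    best_n = max(len(cl) for cl in clusters)
    top = [cl for cl in clusters if len(cl) == best_n]
    tie = len(top) > 1
    winner = max(top, key=lambda cl: sum(s.dwell_s for s in cl))
    lat = sum(s.centroid_lat for s in winner) / len(winner)
    lon = sum(s.centroid_lon for s in winner) / len(winner)
    return HomeInference(gpn=(lat, lon), nights_observed=nights,
                         modal_share=best_n / nights, tie=tie)


def reconcile_home(gpn: tuple[float, float] | None,
                   declared_point: tuple[float, float] | None,
                   cfg: HomeConfig = HomeConfig()) -> HomeDecision:
    """SDN/GPN reconciliation with the 100-m rule.

    The declared (geocoded postal) point is the default home either way;
    a deviation beyond the threshold raises review_flag as the machine
    analogue of manual map inspection.  If one point is absent the other
    wins, flagged.
    """
    if gpn is None and declared_point is None:
        raise ValueError("cannot reconcile: both GPN and SDN absent")
    if declared_point is None:
        return HomeDecision(home=gpn, source="GPN", review_flag=True,
                            deviation_m=None, missing_sdn=True)
    if gpn is None:
        return HomeDecision(home=declared_point, source="SDN", review_flag=True,
                            deviation_m=None, missing_gpn=True)
    dev = geodesic_m(gpn[0], gpn[1], declared_point[0], declared_point[1])
    return HomeDecision(home=declared_point, source="SDN",
                        review_flag=dev > cfg.snap_threshold_m, deviation_m=dev)


def vertical_trips(pressure: Sequence[tuple[dt.datetime, float]],
                   fixes: Sequence[GpsFix],
                   home: tuple[float, float] | None,
                   cfg: BaroConfig = BaroConfig()) -> VerticalResult:
    """Floor transitions from rapid barometric changes anchored at home.

    A maximal run of consecutive pressure intervals whose rate magnitude is
    >= min_rate_hpa_per_10s, with a single sign, is an event when the phone
    is within horizontal_still_radius_m of home at the event midpoint.
    floors_delta = round(-dP * meters_per_hpa / floor_height_m); positive
    means ascent.  Slow weather drift falls below the rate gate.
    """
    if not pressure:
        return VerticalResult([], 0, 0, has_pressure=False)
    samples = sorted(pressure, key=lambda s: s[0])
    rates = []  # (i, sign) for interval i -> i+1
    for i in range(len(samples) - 1):
        (t0, p0), (t1, p1) = samples[i], samples[i + 1]
        span = (t1 - t0).total_seconds()
        if span <= 0:
            rates.append(0)
            continue
        rate = (p1 - p0) / span * 10.0
        if abs(rate) >= cfg.min_rate_hpa_per_10s:
            rates.append(1 if rate > 0 else -1)
        else:
            rates.append(0)

    events: list[VerticalEvent] = []
    i = 0
    while i < len(rates):
        sign = rates[i]
        if sign == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(rates) and rates[j + 1] == sign:
            j += 1
        t_start, p_start = samples[i]
        t_end, p_end = samples[j + 1]
        mid = t_start + (t_end - t_start) / 2
        if home is None or _near_home_at(fixes, mid, home, cfg):
            dp = p_end - p_start
            floors = round(-dp * cfg.meters_per_hpa / cfg.floor_height_m)
            events.append(VerticalEvent(t=mid, floors_delta=floors, delta_hpa=dp))
        i = j + 1

    up = sum(e.floors_delta for e in events if e.floors_delta > 0)
    down = -sum(e.floors_delta for e in events if e.floors_delta < 0)
    return VerticalResult(events=events, total_floors_up=up, total_floors_down=down)


def _near_home_at(fixes: Sequence[GpsFix], t: dt.datetime,
                  home: tuple[float, float], cfg: BaroConfig,
                  max_gap_s: float = 300.0) -> bool:
    best, best_gap = None, math.inf
    for f in fixes:
        gap = abs((f.t - t).total_seconds())
        if gap < best_gap:
            best, best_gap = f, gap
    if best is None or best_gap > max_gap_s:
        return False
    return geodesic_m(best.lat, best.lon, home[0], home[1]) <= cfg.horizontal_still_radius_m
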