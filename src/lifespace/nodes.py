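"""Node-side life-space outcomes: frequency, diversity, duration, complexity.

Complexity is operationalized as the mean pairwise Jensen-Shannon divergence
between per-period (typically per-day) category distributions, normalized by
ln 2 so it lies in [0, 1]: 0 when every period has the same mix, 1 when
periods have disjoint support.  Weights may be visit counts or dwell seconds.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import LOCAL_TZ, StayNode

SEGMENT_KINDS = ("all", "day", "night", "weekday", "weekend")


@dataclass(frozen=True)
class TimeSegment:
    """A recurring slice of the week: all, day/night or weekday/weekend.

    Day is [day_start, day_end) on the local clock; night is its complement.
    """

    kind: str = "all"
    day_start: dt.time = dt.time(6, 0)
    day_end: dt.time = dt.time(22, 0)

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.day_start >= self.day_end:
            raise ValueError("day_start must precede day_end")

    def clip_s(self, start: dt.datetime, end: dt.datetime) -> float:
        """Seconds of [start, end) falling inside this segment."""
        if end <= start:
            return 0.0
        start = start.astimezone(LOCAL_TZ)
        end = end.astimezone(LOCAL_TZ)
        if self.kind == "all":
            return (end - start).total_seconds()
        total = 0.0
        d = start.date()
        while d <= end.date():
            for w0, w1 in self._windows(d):
                lo, hi = max(start, w0), min(end, w1)
                if hi > lo:
                    total += (hi - lo).total_seconds()
            d += dt.timedelta(days=1)
        return total

    def _windows(self, d: dt.date) -> list[tuple[dt.datetime, dt.datetime]]:
        midnight = dt.datetime.combine(d, dt.time(0), tzinfo=LOCAL_TZ)
        next_mid = midnight + dt.timedelta(days=1)
        ds = dt.datetime.combine(d, self.day_start, tzinfo=LOCAL_TZ)
        de = dt.datetime.combine(d, self.day_end, tzinfo=LOCAL_TZ)
        if self.kind == "day":
            return [(ds, de)]
        if self.kind == "night":
            return [(midnight, ds), (de, next_mid)]
        if self.kind == "weekday":
            return [(midnight, next_mid)] if d.weekday() < 5 else []
        if self.kind == "weekend":
            return [(midnight, next_mid)] if d.weekday() >= 5 else []
        return [(midnight, next_mid)]

    def contains_visit(self, stop: StayNode) -> bool:
        return self.clip_s(stop.arrive_t, stop.depart_t) > 0.0

    def contains_instant(self, t: dt.datetime) -> bool:
        return self.clip_s(t, t + dt.timedelta(seconds=1)) > 0.0


@dataclass(frozen=True)
class ComplexityConfig:
    K: int = 14
    weighting: str = "visit_count"  # or "dwell_duration"

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.weighting not in ("visit_count", "dwell_duration"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass
class NodeCounts:
    frequency: int
    diversity: int
    by_type: dict[str, int]


@dataclass
class NodeDurations:
    total_s: float
    by_type: dict[str, float]
    mean_per_visit_s: float


def _activity_stops(stops: Sequence[StayNode], include_home: bool) -> list[StayNode]:
    return [s for s in stops if include_home or not (s.is_home or s.node_type == "home")]


def node_counts(stops: Sequence[StayNode], segment: TimeSegment = TimeSegment(),
                include_home: bool = False) -> NodeCounts:
    """Visit frequency and type diversity of stops intersecting the segment.

    Home stays are excluded by default; each stop episode counts once.
    """
    by_type: dict[str, int] = {}
    for s in _activity_stops(stops, include_home):
        if segment.contains_visit(s):
            by_type[s.node_type] = by_type.get(s.node_type, 0) + 1
    return NodeCounts(frequency=sum(by_type.values()), diversity=len(by_type),
                      by_type=by_type)


def node_durations(stops: Sequence[StayNode], segment: TimeSegment = TimeSegment(),
                   include_home: bool = False) -> NodeDurations:
    """Dwell time credited to the segment (intervals clipped at its edges)."""
    by_type: dict[str, float] = {}
    n_visits = 0
    for s in _activity_stops(stops, include_home):
        clipped = segment.clip_s(s.arrive_t, s.depart_t)
        if clipped > 0:
            by_type[s.node_type] = by_type.get(s.node_type, 0.0) + clipped
            n_visits += 1
    total = sum(by_type.values())
    return NodeDurations(total_s=total, by_type=by_type,
                         mean_per_visit_s=total / n_visits if n_visits else 0.0)


def normalized_entropy(weights: Mapping[str, float],
                       cfg: ComplexityConfig = ComplexityConfig()) -> float:
    """Shannon entropy of the normalized weights, divided by ln(K).

    0 for a point mass, 1 for a uniform spread over all K categories.
    """
    w = np.array([v for v in weights.values() if v > 0], dtype=float)
    if any(v < 0 for v in weights.values()):
        raise ValueError("weights must be non-negative")
    if w.size == 0:
        raise ValueError("weights must not all be zero")
    p = w / w.sum()
    h = float(-(p * np.log(p)).sum())
    return h / math.log(cfg.K)


def _jsd_nats(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in nats; max ln 2 at disjoint support."""
    m = (p + q) / 2
    def kl(a, b):
        mask = a > 0
        return float((a[mask] * np.log(a[mask] / b[mask])).sum())
    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def complexity(per_period_weights: Sequence[Mapping[str, float]],
               cfg: ComplexityConfig = ComplexityConfig()) -> float:
    """Cross-period variability: mean pairwise JSD between period
    distributions, normalized by ln 2.  Periods with zero total weight are
    ignored; fewer than 2 usable periods is an error."""
    cats = sorted({k for w in per_period_weights for k in w})
    dists = []
    for w in per_period_weights:
        v = np.array([max(0.0, w.get(c, 0.0)) for c in cats], dtype=float)
        if v.sum() > 0:
            dists.append(v / v.sum())
    if len(dists) < 2:
        raise ValueError("complexity needs at least 2 periods with nonzero weight")
    total, n_pairs = 0.0, 0
    for i in range(len(dists)):
        for j in range(i + 1, len(dists)):
            total += _jsd_nats(dists[i], dists[j])
            n_pairs += 1
    return total / n_pairs / math.log(2)


def node_complexity(per_period_weights: Sequence[Mapping[str, float]],
                    cfg: ComplexityConfig = ComplexityConfig()) -> float:
    return complexity(per_period_weights, cfg)


def daily_type_weights(stops_by_day: Sequence[Sequence[StayNode]],
                       cfg: ComplexityConfig = ComplexityConfig(),
                       include_home: bool = False) -> list[dict[str, float]]:
    """Per-day node-type weight maps (visit counts or dwell seconds)."""
    out = []
    for stops in stops_by_day:
        w: dict[str, float] = {}
        for s in _activity_stops(stops, include_home):
            inc = 1.0 if cfg.weighting == "visit_count" else s.dwell_s
            w[s.node_type] = w.get(s.node_type, 0.0) + inc
        out.append(w)
    return out
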