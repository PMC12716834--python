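"""Domain model for smartphone travel-diary life-space mobility data.

The objects here mirror the structure of a 14-day validated travel diary:
timestamped GPS fixes, detected stay nodes typed by a 14-category activity
taxonomy, mode-typed trips between nodes, and per-day validity flags.
All invariants are enforced at construction; downstream code may assume
well-formed objects.

Conventions
-----------
* Coordinates are WGS84 decimal degrees.
* Timestamps carry a UTC offset; day boundaries are computed in the
  participant's local zone (default UTC+08:00).
* Time intervals are half-open ``[arrive, depart)``.
"""

from __future__ import annotations

import datetime as dt
import io
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: Local timezone used for day boundaries (Singapore Standard Time).
LOCAL_TZ = dt.timezone(dt.timedelta(hours=8))

#: Default geographic validity box (Singapore and surrounding waters).
DEFAULT_BOUNDS = (1.1, 1.5, 103.55, 104.15)  # lat_min, lat_max, lon_min, lon_max

#: Default 14-code activity-node taxonomy.  The exact display labels are a
#: deployment choice; the taxonomy is replaceable via :class:`Taxonomy`.
DEFAULT_NODE_TYPES = (
    "home", "work", "dining", "shopping", "market", "recreation",
    "exercise", "healthcare", "social", "religious", "education",
    "errand", "escort", "other",
)

FIX_SOURCES = frozenset({"gps", "wifi", "cell", "manual"})

MODE_CODES = (
    "walk", "bicycle", "bus", "train", "car_driver", "car_passenger",
    "taxi", "motorcycle", "motorized_unspecified", "other",
)
ACTIVE_MODES = frozenset({"walk", "bicycle"})

INVALID_REASONS = frozenset(
    {"none", "no_device", "out_of_country", "declared_invalid", "no_data"}
)


class ValidationError(ValueError):
    """An object violated a structural invariant; names the offending field."""


@dataclass(frozen=True)
class Taxonomy:
    """Activity-node taxonomy: exactly 14 unique codes, one of them 'home'."""

    codes: tuple[str, ...] = DEFAULT_NODE_TYPES
    labels: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.codes) != 14:
            raise ValidationError(f"taxonomy must have exactly 14 codes, got {len(self.codes)}")
        if len(set(self.codes)) != len(self.codes):
            raise ValidationError("taxonomy codes must be unique")
        if "home" not in self.codes:
            raise ValidationError("taxonomy must include a 'home' code")

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def label(self, code: str) -> str:
        if self.labels and code in self.labels:
            return self.labels[code]
        return code.replace("_", " ").title()

    @property
    def size(self) -> int:
        return len(self.codes)


DEFAULT_TAXONOMY = Taxonomy()


@dataclass(frozen=True)
class TravelMode:
    """A transport mode; walking and bicycling are the active modes."""

    code: str

    def __post_init__(self) -> None:
        if self.code not in MODE_CODES:
            raise ValidationError(f"unknown travel mode {self.code!r}")

    @property
    def active(self) -> bool:
        return self.code in ACTIVE_MODES


def is_active_mode(code: str) -> bool:
    return code in ACTIVE_MODES


@dataclass(frozen=True)
class GpsFix:
    participant_id: str
    t: dt.datetime
    lat: float
    lon: float
    accuracy_m: float | None = None
    altitude_m: float | None = None
    pressure_hpa: float | None = None
    source: str = "gps"

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"lat out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"lon out of range: {self.lon}")
        if self.accuracy_m is not None and self.accuracy_m < 0:
            raise ValidationError(f"accuracy_m must be >= 0, got {self.accuracy_m}")
        if self.t.tzinfo is None:
            raise ValidationError("fix timestamp must carry a UTC offset")
        if self.source not in FIX_SOURCES:
            raise ValidationError(f"unknown fix source {self.source!r}")


@dataclass(frozen=True)
class StayNode:
    """A detected or diary-validated stop with a dwell interval."""

    node_id: str
    centroid_lat: float
    centroid_lon: float
    arrive_t: dt.datetime
    depart_t: dt.datetime
    node_type: str = "other"
    signature_id: str | None = None
    is_home: bool = False

    def __post_init__(self) -> None:
        if self.depart_t <= self.arrive_t:
            raise ValidationError(f"depart_t must follow arrive_t for node {self.node_id}")
        if not -90.0 <= self.centroid_lat <= 90.0:
            raise ValidationError(f"centroid_lat out of range: {self.centroid_lat}")
        if not -180.0 <= self.centroid_lon <= 180.0:
            raise ValidationError(f"centroid_lon out of range: {self.centroid_lon}")

    @property
    def dwell_s(self) -> float:
        return (self.depart_t - self.arrive_t).total_seconds()


@dataclass(frozen=True)
class TripLeg:
    """One mode-homogeneous segment of a trip.

    ``linear_m`` is the geodesic origin->destination distance; ``path_m`` the
    distance summed along the recorded fixes.  ``path_m >= linear_m - eps``
    by the triangle inequality (eps absorbs GPS noise on short legs).
    """

    start_t: dt.datetime
    end_t: dt.datetime
    mode: str
    path: tuple[GpsFix, ...] = ()
    linear_m: float = 0.0
    path_m: float = 0.0

    _NOISE_EPS_M = 25.0

    def __post_init__(self) -> None:
        if self.end_t <= self.start_t:
            raise ValidationError("leg end_t must follow start_t")
        if self.mode not in MODE_CODES:
            raise ValidationError(f"unknown travel mode {self.mode!r}")
        if self.path_m < self.linear_m - self._NOISE_EPS_M:
            raise ValidationError(
                f"path_m ({self.path_m:.1f}) < linear_m ({self.linear_m:.1f}) beyond noise eps"
            )
        for a, b in zip(self.path, self.path[1:]):
            if b.t < a.t:
                raise ValidationError("leg path must be chronological")

    @property
    def duration_s(self) -> float:
        return (self.end_t - self.start_t).total_seconds()

    @property
    def active(self) -> bool:
        return self.mode in ACTIVE_MODES


@dataclass(frozen=True)
class Trip:
    """Movement between two activity nodes, partitioned into mode legs.

    Legs are ordered and non-overlapping; the dwell at an intermediate
    transfer stop falls in the gap between consecutive legs.
    """

    origin: StayNode
    destination: StayNode
    legs: tuple[TripLeg, ...]

    def __post_init__(self) -> None:
        if not self.legs:
            raise ValidationError("trip must have at least one leg")
        for a, b in zip(self.legs, self.legs[1:]):
            if b.start_t < a.end_t:
                raise ValidationError("trip legs must not overlap in time")

    @property
    def start_t(self) -> dt.datetime:
        return self.legs[0].start_t

    @property
    def end_t(self) -> dt.datetime:
        return self.legs[-1].end_t

    @property
    def modes(self) -> tuple[str, ...]:
        return tuple(leg.mode for leg in self.legs)

    @property
    def main_mode(self) -> str:
        """Mode of the longest-duration leg (ties broken by leg order)."""
        return max(self.legs, key=lambda leg: leg.duration_s).mode


@dataclass(frozen=True)
class DiaryDay:
    date: dt.date
    fixes: tuple[GpsFix, ...] = ()
    stops: tuple[StayNode, ...] = ()
    trips: tuple[Trip, ...] = ()
    valid: bool = True
    invalid_reason: str = "none"

    def __post_init__(self) -> None:
        if self.invalid_reason not in INVALID_REASONS:
            raise ValidationError(f"unknown invalid_reason {self.invalid_reason!r}")
        if self.valid and self.invalid_reason != "none":
            raise ValidationError("valid day must have invalid_reason 'none'")
        for a, b in zip(self.stops, self.stops[1:]):
            if b.arrive_t < a.depart_t:
                raise ValidationError("stops must not overlap in time")
        for trip in self.trips:
            if trip.end_t < trip.start_t:
                raise ValidationError("trip interval malformed")


@dataclass(frozen=True)
class ParticipantDiary:
    participant_id: str
    days: tuple[DiaryDay, ...]
    home: StayNode | None = None
    declared_postal_point: tuple[float, float] | None = None
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.days) != 14:
            raise ValidationError(f"diary must have exactly 14 days, got {len(self.days)}")
        for a, b in zip(self.days, self.days[1:]):
            if (b.date - a.date).days != 1:
                raise ValidationError("diary days must be consecutive")

    @property
    def complete(self) -> bool:
        return all(day.valid for day in self.days)

    @property
    def all_stops(self) -> tuple[StayNode, ...]:
        return tuple(s for day in self.days for s in day.stops)

    @property
    def all_trips(self) -> tuple[Trip, ...]:
        return tuple(t for day in self.days for t in day.trips)


@dataclass
class MetricsReport:
    """Flat map of named life-space outcomes for one participant.

    Keys follow ``<family>.<metric>.<segment>`` (e.g. ``node.frequency.all``,
    ``trip.active_share.weekday``, ``extent.convex_hull_km2.all``).
    """

    participant_id: str
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.metrics.items():
            if ("area" in key or "km2" in key) and value < 0:
                raise ValidationError(f"negative area for {key}")

    def to_json(self) -> str:
        return json.dumps(
            {"schema_version": SCHEMA_VERSION,
             "participant_id": self.participant_id,
             "metrics": self.metrics},
            indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Fix CSV I/O
# ---------------------------------------------------------------------------

REQUIRED_FIX_COLUMNS = ("id", "timestamp", "lat", "lon")
OPTIONAL_FIX_COLUMNS = ("accuracy", "altitude", "pressure", "source")


@dataclass
class ParseResult:
    fixes: dict[str, list[GpsFix]]
    n_dropped: int
    drop_reasons: list[tuple[int, str]]  # (row index, reason)


def parse_fixes(csv_source) -> ParseResult:
    """Read a fix CSV into per-participant, time-sorted fix lists.

    Malformed rows (bad coordinates, unparseable timestamps) are dropped and
    logged, not fatal.  Duplicate timestamps within a participant collapse
    last-wins.  Raises :class:`ValidationError` if a required column is
    missing.
    """
    df = pd.read_csv(csv_source, dtype={"id": str})
    missing = [c for c in REQUIRED_FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"fix CSV missing required column(s): {', '.join(missing)}")

    drops: list[tuple[int, str]] = []
    rows: dict[str, dict[dt.datetime, GpsFix]] = {}
    for idx, row in df.iterrows():
        try:
            t = _parse_timestamp(row["timestamp"])
        except (ValueError, TypeError):
            drops.append((int(idx), "bad_timestamp"))
            continue
        try:
            fix = GpsFix(
                participant_id=str(row["id"]),
                t=t,
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                accuracy_m=_opt_float(row.get("accuracy")),
                altitude_m=_opt_float(row.get("altitude")),
                pressure_hpa=_opt_float(row.get("pressure")),
                source=str(row.get("source", "gps")) if pd.notna(row.get("source", "gps")) else "gps",
            )
        except (ValidationError, ValueError) as exc:
            drops.append((int(idx), str(exc)))
            continue
        rows.setdefault(fix.participant_id, {})[fix.t] = fix  # last-wins on duplicates

    for idx, reason in drops:
        logger.warning("dropped fix row %d: %s", idx, reason)
    fixes = {pid: [by_t[t] for t in sorted(by_t)] for pid, by_t in rows.items()}
    return ParseResult(fixes=fixes, n_dropped=len(drops), drop_reasons=drops)


def fixes_to_csv(fixes: Iterable[GpsFix], path: str | Path | None = None) -> str:
    """Serialize fixes to the canonical CSV dialect; returns the text."""
    records = []
    for f in fixes:
        records.append({
            "id": f.participant_id,
            "timestamp": f.t.isoformat(),
            "lat": f.lat,
            "lon": f.lon,
            "accuracy": f.accuracy_m,
            "altitude": f.altitude_m,
            "pressure": f.pressure_hpa,
            "source": f.source,
        })
    df = pd.DataFrame.from_records(
        records, columns=["id", "timestamp", "lat", "lon", "accuracy",
                          "altitude", "pressure", "source"])
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def _parse_timestamp(value) -> dt.datetime:
    if isinstance(value, dt.datetime):
        t = value
    else:
        t = dt.datetime.fromisoformat(str(value))
    if t.tzinfo is None:
        t = t.replace(tzinfo=LOCAL_TZ)
    return t


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return None
    return float(value)


# ---------------------------------------------------------------------------
# Diary JSON round-trip
# ---------------------------------------------------------------------------

def diary_to_json(diary: ParticipantDiary) -> str:
    return json.dumps(_diary_to_obj(diary), indent=2)


def diary_from_json(text: str) -> ParticipantDiary:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"diary JSON unreadable: {exc}") from exc
    try:
        return _diary_from_obj(obj)
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"diary JSON missing field: {exc}") from exc


def save_diary(diary: ParticipantDiary, path: str | Path) -> None:
    Path(path).write_text(diary_to_json(diary))


def load_diary(path: str | Path) -> ParticipantDiary:
    return diary_from_json(Path(path).read_text())


def _fix_to_obj(f: GpsFix) -> dict:
    return {"id": f.participant_id, "t": f.t.isoformat(), "lat": f.lat, "lon": f.lon,
            "accuracy_m": f.accuracy_m, "altitude_m": f.altitude_m,
            "pressure_hpa": f.pressure_hpa, "source": f.source}


def _fix_from_obj(o: dict) -> GpsFix:
    return GpsFix(participant_id=o["id"], t=dt.datetime.fromisoformat(o["t"]),
                  lat=o["lat"], lon=o["lon"], accuracy_m=o.get("accuracy_m"),
                  altitude_m=o.get("altitude_m"), pressure_hpa=o.get("pressure_hpa"),
                  source=o.get("source", "gps"))


def _stop_to_obj(s: StayNode) -> dict:
    return {"node_id": s.node_id, "lat": s.centroid_lat, "lon": s.centroid_lon,
            "arrive_t": s.arrive_t.isoformat(), "depart_t": s.depart_t.isoformat(),
            "node_type": s.node_type, "signature_id": s.signature_id,
            "is_home": s.is_home}


def _stop_from_obj(o: dict) -> StayNode:
    return StayNode(node_id=o["node_id"], centroid_lat=o["lat"], centroid_lon=o["lon"],
                    arrive_t=dt.datetime.fromisoformat(o["arrive_t"]),
                    depart_t=dt.datetime.fromisoformat(o["depart_t"]),
                    node_type=o.get("node_type", "other"),
                    signature_id=o.get("signature_id"), is_home=o.get("is_home", False))


def _diary_to_obj(diary: ParticipantDiary) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "participant_id": diary.participant_id,
        "declared_postal_point": list(diary.declared_postal_point) if diary.declared_postal_point else None,
        "home": _stop_to_obj(diary.home) if diary.home else None,
        "metadata": dict(diary.metadata),
        "days": [
            {
                "date": day.date.isoformat(),
                "valid": day.valid,
                "invalid_reason": day.invalid_reason,
                "fixes": [_fix_to_obj(f) for f in day.fixes],
                "stops": [_stop_to_obj(s) for s in day.stops],
                "trips": [
                    {
                        "origin": _stop_to_obj(t.origin),
                        "destination": _stop_to_obj(t.destination),
                        "legs": [
                            {"start_t": leg.start_t.isoformat(),
                             "end_t": leg.end_t.isoformat(),
                             "mode": leg.mode,
                             "linear_m": leg.linear_m,
                             "path_m": leg.path_m,
                             "path": [_fix_to_obj(f) for f in leg.path]}
                            for leg in t.legs
                        ],
                    }
                    for t in day.trips
                ],
            }
            for day in diary.days
        ],
    }


def _diary_from_obj(obj: dict) -> ParticipantDiary:
    days = []
    for d in obj["days"]:
        trips = []
        for t in d.get("trips", ()):
            legs = tuple(
                TripLeg(start_t=dt.datetime.fromisoformat(l["start_t"]),
                        end_t=dt.datetime.fromisoformat(l["end_t"]),
                        mode=l["mode"],
                        path=tuple(_fix_from_obj(f) for f in l.get("path", ())),
                        linear_m=l.get("linear_m", 0.0), path_m=l.get("path_m", 0.0))
                for l in t["legs"])
            trips.append(Trip(origin=_stop_from_obj(t["origin"]),
                              destination=_stop_from_obj(t["destination"]), legs=legs))
        days.append(DiaryDay(
            date=dt.date.fromisoformat(d["date"]),
            fixes=tuple(_fix_from_obj(f) for f in d.get("fixes", ())),
            stops=tuple(_stop_from_obj(s) for s in d.get("stops", ())),
            trips=tuple(trips),
            valid=d["valid"], invalid_reason=d.get("invalid_reason", "none")))
    declared = obj.get("declared_postal_point")
    return ParticipantDiary(
        participant_id=obj["participant_id"],
        days=tuple(days),
        home=_stop_from_obj(obj["home"]) if obj.get("home") else None,
        declared_postal_point=tuple(declared) if declared else None,
        metadata=obj.get("metadata", {}))


# ---------------------------------------------------------------------------
# Day validation
# ---------------------------------------------------------------------------

def validate_day(
    day: DiaryDay,
    bounds: tuple[float, float, float, float] = DEFAULT_BOUNDS,
    declared_flags: frozenset[str] | set[str] = frozenset(),
) -> DiaryDay:
    """Classify a diary day as valid or invalid with a reason.

    Precedence: any fix outside ``bounds`` -> out_of_country; a declared
    flag ('declared_invalid' or 'no_device') -> that flag; zero fixes ->
    no_data; otherwise valid.  Total and idempotent.
    """
    lat_min, lat_max, lon_min, lon_max = bounds
    out = any(not (lat_min <= f.lat <= lat_max and lon_min <= f.lon <= lon_max)
              for f in day.fixes)
    if out:
        reason = "out_of_country"
    elif "declared_invalid" in declared_flags:
        reason = "declared_invalid"
    elif "no_device" in declared_flags:
        reason = "no_device"
    elif not day.fixes:
        reason = "no_data"
    else:
        reason = "none"
    return replace(day, valid=(reason == "none"), invalid_reason=reason)


def cohort_percentage(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of a cohort count over a denominator, rounded for reporting."""
    if total <= 0:
        raise ValidationError("denominator must be positive")
    return round(100.0 * count / total, ndigits)


def stops_to_geojson(stops: Iterable[StayNode]) -> str:
    """Export stay nodes as an RFC 7946 FeatureCollection for GIS overlay."""
    features = []
    for s in stops:
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [s.centroid_lon, s.centroid_lat]},
            "properties": {"node_id": s.node_id, "node_type": s.node_type,
                           "arrive_t": s.arrive_t.isoformat(),
                           "depart_t": s.depart_t.isoformat(),
                           "dwell_s": s.dwell_s, "is_home": s.is_home,
                           "signature_id": s.signature_id},
        })
    return json.dumps({"type": "FeatureCollection", "features": features},
                      indent=2)
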