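"""Scorers for the in-person geriatric assessment battery, plus the
correlation power / sample-size calculation used for study design.

Implemented instruments
-----------------------
* Composite life-space assessment (UAB-LSA style): per level 1-5,
  score += level x independence weight (1 / 1.5 / 2) x frequency weight
  (1..4); maximum 120; scores below 60 flag restricted life space.
* Fried phenotype / FRAIL scale: count of 5 positive items; 0 robust,
  1-2 prefrail, 3-5 frail.
* IPAQ short form: MET-minutes/week with multipliers 8.0 (vigorous),
  4.0 (moderate), 3.3 (walking); sitting time reported separately.
* Lubben social network scale (12 items, 0-5 each, max 60; <20 flags
  social isolation risk), 15-item geriatric depression scale (keyed
  yes/no items; 5-9 suggests depression, >=10 indicative), 3-item UCLA
  loneliness scale (0-4 each, total 0-12).
* EQ-5D-5L profile string construction (index-value crosswalks are an
  external value set and out of scope).

Power: Fisher-z normal approximation,
power = Phi(|atanh r| * sqrt(n - 3) - z_{1-alpha/2}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import norm

INDEPENDENCE_WEIGHTS = {"personal_assistance": 1.0, "equipment_only": 1.5,
                        "independent": 2.0}
FREQUENCY_WEIGHTS = {"lt1_per_week": 1, "1_3_per_week": 2,
                     "4_6_per_week": 3, "daily": 4}

#: Standard 15-item geriatric depression scale keying: indices (0-based) of
#: the positively worded items, for which "no" scores the point.
GDS15_POSITIVE_ITEMS = frozenset({0, 4, 6, 10, 12})

FRIED_ITEMS = ("weight_loss", "exhaustion", "physical_activity",
               "walk_time", "grip_strength")
FRAIL_ITEMS = ("fatigue", "resistance", "ambulation", "illness", "loss_of_weight")

IPAQ_MET = {"vigorous": 8.0, "moderate": 4.0, "walking": 3.3}


@dataclass(frozen=True)
class LsaLevel:
    attained: bool
    independence: str = "independent"
    frequency: str = "daily"

    def __post_init__(self) -> None:
        if self.independence not in INDEPENDENCE_WEIGHTS:
            raise ValueError(f"unknown independence code {self.independence!r}")
        if self.frequency not in FREQUENCY_WEIGHTS:
            raise ValueError(f"unknown frequency code {self.frequency!r}")


@dataclass(frozen=True)
class LsaResponse:
    levels: tuple[LsaLevel, LsaLevel, LsaLevel, LsaLevel, LsaLevel]

    def __post_init__(self) -> None:
        if len(self.levels) != 5:
            raise ValueError("life-space response needs exactly 5 levels")


@dataclass
class LsaScore:
    score: float
    restricted: bool


def score_uab_lsa(resp: LsaResponse,
                  independence_weights: Mapping[str, float] = INDEPENDENCE_WEIGHTS,
                  frequency_weights: Mapping[str, int] = FREQUENCY_WEIGHTS,
                  restricted_cutoff: float = 60.0) -> LsaScore:
    """Composite life-space score: sum over attained levels of
    level x independence x frequency.  Unattained levels contribute 0."""
    total = 0.0
    for level_num, level in enumerate(resp.levels, start=1):
        if level.attained:
            total += (level_num * independence_weights[level.independence]
                      * frequency_weights[level.frequency])
    return LsaScore(score=total, restricted=total < restricted_cutoff)


@dataclass(frozen=True)
class FrailtyResponse:
    instrument: str  # "fried" | "frail"
    items: tuple[bool, bool, bool, bool, bool]

    def __post_init__(self) -> None:
        if self.instrument not in ("fried", "frail"):
            raise ValueError(f"unknown frailty instrument {self.instrument!r}")
        if len(self.items) != 5:
            raise ValueError("frailty screen needs exactly 5 items")


@dataclass
class FrailtyResult:
    score: int
    category: str  # robust | prefrail | frail


def classify_frailty(resp: FrailtyResponse) -> FrailtyResult:
    score = sum(resp.items)
    if score == 0:
        category = "robust"
    elif score <= 2:
        category = "prefrail"
    else:
        category = "frail"
    return FrailtyResult(score=score, category=category)


@dataclass(frozen=True)
class IpaqResponse:
    days_per_week: Mapping[str, int]      # keys: vigorous, moderate, walking
    minutes_per_day: Mapping[str, float]
    sitting_min_per_weekday: float = 0.0

    def __post_init__(self) -> None:
        for intensity in IPAQ_MET:
            d = self.days_per_week.get(intensity, 0)
            m = self.minutes_per_day.get(intensity, 0.0)
            if not 0 <= d <= 7:
                raise ValueError(f"{intensity}: days_per_week must be 0..7")
            if m < 0 or self.sitting_min_per_weekday < 0:
                raise ValueError("minutes must be non-negative")


@dataclass
class IpaqResult:
    total_met_min_per_week: float
    by_intensity: dict[str, float]
    sitting_min_per_weekday: float


def score_ipaq_met(resp: IpaqResponse) -> IpaqResult:
    by = {intensity: (met * resp.minutes_per_day.get(intensity, 0.0)
                      * resp.days_per_week.get(intensity, 0))
          for intensity, met in IPAQ_MET.items()}
    return IpaqResult(total_met_min_per_week=sum(by.values()), by_intensity=by,
                      sitting_min_per_weekday=resp.sitting_min_per_weekday)


@dataclass
class LsnsScore:
    total: int
    isolated: bool


def score_lsns(items: Sequence[int], isolation_cutoff: int = 20) -> LsnsScore:
    """12-item social network scale; items 0-5; total 0-60; <20 flags risk."""
    if len(items) != 12:
        raise ValueError(f"social network scale needs 12 items, got {len(items)}")
    if any(not 0 <= v <= 5 for v in items):
        raise ValueError("social network scale items must be 0..5")
    total = int(sum(items))
    return LsnsScore(total=total, isolated=total < isolation_cutoff)


@dataclass
class GdsScore:
    total: int
    band: str  # normal | suggests_depression | indicative_of_depression


def score_gds(yes_answers: Sequence[bool],
              positive_items: frozenset[int] = GDS15_POSITIVE_ITEMS) -> GdsScore:
    """15-item depression screen.  'Yes' to a negatively worded item scores 1;
    'no' to a positively worded item scores 1.  Keying is configurable."""
    if len(yes_answers) != 15:
        raise ValueError(f"depression screen needs 15 items, got {len(yes_answers)}")
    total = sum((not ans) if i in positive_items else bool(ans)
                for i, ans in enumerate(yes_answers))
    if total >= 10:
        band = "indicative_of_depression"
    elif total >= 5:
        band = "suggests_depression"
    else:
        band = "normal"
    return GdsScore(total=total, band=band)


def score_ucla(items: Sequence[int]) -> int:
    """3-item loneliness scale; items 0 ('never') .. 4 ('always'); total 0-12."""
    if len(items) != 3:
        raise ValueError(f"loneliness scale needs 3 items, got {len(items)}")
    if any(not 0 <= v <= 4 for v in items):
        raise ValueError("loneliness items must be 0..4")
    return int(sum(items))


def eq5d_profile(levels: Sequence[int]) -> str:
    """Concatenate the five 1-5 dimension levels into a profile ('11111'...)."""
    if len(levels) != 5 or any(not 1 <= v <= 5 for v in levels):
        raise ValueError("EQ-5D-5L profile needs five levels in 1..5")
    return "".join(str(v) for v in levels)


def score_scales(responses: Mapping[str, Sequence]) -> dict[str, object]:
    """Batch dispatch: keys 'lsns', 'gds', 'ucla' -> per-instrument records."""
    out: dict[str, object] = {}
    if "lsns" in responses:
        out["lsns"] = score_lsns(responses["lsns"])
    if "gds" in responses:
        out["gds"] = score_gds(responses["gds"])
    if "ucla" in responses:
        out["ucla"] = score_ucla(responses["ucla"])
    return out


# ---------------------------------------------------------------------------
# Correlation power (Fisher z)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerQuery:
    r: float
    alpha: float = 0.05
    n: int | None = None
    power: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ValueError("r must be in (0, 1)")
        if (self.n is None) == (self.power is None):
            raise ValueError("exactly one of n / power must be given")


def correlation_power(q: PowerQuery) -> dict[str, float | int]:
    """Power or minimum n for a two-sided test of a Pearson correlation.

    Fisher-z normal approximation:
    power = Phi(|atanh r| * sqrt(n - 3) - z_{1 - alpha/2}).
    Solving for n inverts the formula and rounds up, then adjusts so the
    returned n is the smallest integer meeting the target.
    """
    z_alpha = norm.ppf(1 - q.alpha / 2)
    zr = abs(math.atanh(q.r))
    if q.n is not None:
        if q.n < 4:
            raise ValueError("n must be at least 4")
        power = float(norm.cdf(zr * math.sqrt(q.n - 3) - z_alpha))
        return {"power": power}
    z_beta = norm.ppf(q.power)
    n = math.ceil(((z_alpha + z_beta) / zr) ** 2 + 3)
    while n > 4 and norm.cdf(zr * math.sqrt(n - 4) - z_alpha) >= q.power:
        n -= 1
    while norm.cdf(zr * math.sqrt(n - 3) - z_alpha) < q.power:
        n += 1
    return {"n": int(n)}
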