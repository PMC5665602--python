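"""Deterministic calculators for four ED physiologic severity scores.

RAPS (Rapid Acute Physiology Score) scores pulse rate, mean arterial
pressure, respiratory rate and Glasgow Coma Scale on 0-4 point bands
(range 0-16).  REMS (Rapid Emergency Medicine Score) extends RAPS with
age and peripheral oxygen saturation (range 0-26).  MEWS (Modified Early
Warning Score) is a track-and-trigger score over systolic blood
pressure, heart rate, respiratory rate, temperature and the AVPU
consciousness scale (range 0-14).  MEDS (Mortality in Emergency
Department Sepsis score) awards weighted points for nine sepsis risk
criteria (range 0-27).

Real-valued vitals are rounded half-up to the integer resolution of the
band tables (temperature to 0.1 degC) before lookup, so e.g. a pulse rate
of 120.5/min is scored as 121/min and a temperature of 38.45 degC as
38.5 degC.  Two published MEWS bands leave one-unit gaps (systolic BP
exactly 70 mmHg, heart rate exactly 40/min); the calculators assign the
adjacent higher-acuity band, a conservative triage convention.

By default a missing required input raises :class:`MissingInputError`;
an opt-in ``impute_normal`` mode substitutes the midpoint of the
zero-point band and logs each substitution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "Avpu",
    "Vitals",
    "MedsCriteria",
    "ScoreBreakdown",
    "MissingInputError",
    "raps_score",
    "rems_score",
    "mews_score",
    "meds_score",
    "tachypnea_or_hypoxia",
    "avpu_from_gcs",
    "SCORE_RANGES",
]

#: Attainable (min, max) total per scoring system.
SCORE_RANGES = {"RAPS": (0, 16), "REMS": (0, 26), "MEWS": (0, 14), "MEDS": (0, 27)}


class MissingInputError(ValueError):
    """A required scoring input is absent."""

    def __init__(self, score: str, field_name: str):
        self.score = score
        self.field_name = field_name
        super().__init__(f"{score} requires '{field_name}' but it is missing")


class Avpu(str, Enum):
    """AVPU consciousness scale: Alert / reacts to Voice / reacts to Pain / Unresponsive."""

    ALERT = "alert"
    VOICE = "voice"
    PAIN = "pain"
    UNRESPONSIVE = "unresponsive"


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from the lower band (half-up), decimal-exact.

    Uses the shortest decimal repr of ``x`` so that e.g. 38.45 (stored in
    binary as 38.44999...) still rounds up to 38.5.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Vitals:
    """One patient's triage vitals.  Unused fields may be None.

    Units: pulse_rate beats/min, respiratory_rate breaths/min,
    systolic_bp and mean_arterial_pressure mmHg, temperature degC,
    spo2 percent, gcs integer 3-15.
    """

    pulse_rate: float | None = None
    respiratory_rate: float | None = None
    systolic_bp: float | None = None
    mean_arterial_pressure: float | None = None
    temperature: float | None = None
    spo2: float | None = None
    gcs: int | None = None
    avpu: Avpu | None = None

    def __post_init__(self):
        for name in ("pulse_rate", "respiratory_rate", "systolic_bp", "mean_arterial_pressure"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be a non-negative finite number, got {v!r}")
        if self.spo2 is not None and not 0 <= self.spo2 <= 100:
            raise ValueError(f"spo2 must lie in [0, 100], got {self.spo2!r}")
        if self.gcs is not None:
            if self.gcs != int(self.gcs) or not 3 <= self.gcs <= 15:
                raise ValueError(f"gcs must be an integer in [3, 15], got {self.gcs!r}")
        if self.temperature is not None and not math.isfinite(self.temperature):
            raise ValueError("temperature must be finite")


@dataclass(frozen=True)
class MedsCriteria:
    """The nine MEDS risk criteria (adult ED patients, age >= 18).

    ``terminal_illness`` means rapidly fatal disease with perceived
    30-day mortality.  ``platelet_count`` is in 1e9 cells/L.  The
    tachypnea-or-hypoxia criterion is not stored: it is derived from the
    vitals and ``oxygen_by_mask``.  ``altered_mental_status`` may be None,
    in which case GCS <= 13 is used as the default proxy.
    """

    age: float
    terminal_illness: bool = False
    septic_shock: bool = False
    platelet_count: float | None = None
    band_percent: float | None = None
    lower_respiratory_infection: bool = False
    nursing_home_resident: bool = False
    altered_mental_status: bool | None = None
    oxygen_by_mask: bool = False

    def __post_init__(self):
        if self.age < 18:
            raise ValueError(f"age must be >= 18 (adult cohort), got {self.age!r}")
        if self.band_percent is not None and not 0 <= self.band_percent <= 100:
            raise ValueError(f"band_percent must lie in [0, 100], got {self.band_percent!r}")
        if self.platelet_count is not None and self.platelet_count < 0:
            raise ValueError("platelet_count must be non-negative")


@dataclass(frozen=True)
class ScoreBreakdown:
    """A score total with per-variable point attribution."""

    system: str
    total: int
    components: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.total != sum(self.components.values()):
            raise ValueError("total must equal the sum of components")
        lo, hi = SCORE_RANGES[self.system]
        if not lo <= self.total <= hi:
            raise ValueError(f"{self.system} total {self.total} outside [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# Band tables.  Each band is (lo, hi, points) over rounded values, with
# inclusive integer bounds (temperature bounds in 0.1 degC).  Bands are
# ordered and jointly cover the whole real line.

_INF = math.inf

_RAPS_PR = [(-_INF, 39, 4), (40, 54, 3), (55, 69, 2), (70, 109, 0), (110, 139, 2), (140, 179, 3), (180, _INF, 4)]
_RAPS_MAP = [(-_INF, 49, 4), (50, 69, 2), (70, 109, 0), (110, 129, 2), (130, 159, 3), (160, _INF, 4)]
_RAPS_RR = [(-_INF, 5, 4), (6, 9, 2), (10, 11, 1), (12, 24, 0), (25, 34, 1), (35, 49, 3), (50, _INF, 4)]
_GCS_BANDS = [(-_INF, 4, 4), (5, 7, 3), (8, 10, 2), (11, 13, 1), (14, _INF, 0)]

_REMS_AGE = [(-_INF, 44, 0), (45, 54, 2), (55, 64, 3), (65, 74, 5), (75, _INF, 6)]
_REMS_SPO2 = [(-_INF, 74, 4), (75, 85, 3), (86, 89, 1), (90, _INF, 0)]

# MEWS: SBP 70 and HR 40 sit in one-unit gaps of the published table;
# they take the adjacent higher-acuity band (+3 and +2 respectively).
_MEWS_SBP = [(-_INF, 70, 3), (71, 80, 2), (81, 100, 1), (101, 199, 0), (200, _INF, 2)]
_MEWS_HR = [(-_INF, 40, 2), (41, 50, 1), (51, 100, 0), (101, 110, 1), (111, 129, 2), (130, _INF, 3)]
_MEWS_RR = [(-_INF, 8, 2), (9, 14, 0), (15, 20, 1), (21, 29, 2), (30, _INF, 3)]
# Temperature in tenths of degC; the published table has no +1 or +3 band.
_MEWS_TEMP10 = [(-_INF, 349, 2), (350, 384, 0), (385, _INF, 2)]
_MEWS_AVPU = {Avpu.ALERT: 0, Avpu.VOICE: 1, Avpu.PAIN: 2, Avpu.UNRESPONSIVE: 3}

# Zero-band midpoints used only by the opt-in impute_normal mode.
_NORMAL_VALUES = {
    "pulse_rate": 90.0,
    "mean_arterial_pressure": 90.0,
    "respiratory_rate": 18.0,
    "gcs": 15,
    "spo2": 95.0,
    "systolic_bp": 150.0,
    "temperature": 36.7,
    "avpu": Avpu.ALERT,
}


def _lookup(bands, value) -> int:
    hits = [pts for lo, hi, pts in bands if lo <= value <= hi]
    if len(hits) != 1:  # bands are exhaustive and disjoint by construction
        raise AssertionError(f"band lookup for {value!r} matched {len(hits)} bands")
    return hits[0]


def _require(score: str, vitals: Vitals, name: str, impute_normal: bool):
    value = getattr(vitals, name)
    if value is None:
        if impute_normal:
            value = _NORMAL_VALUES[name]
            logger.info("%s: imputing normal %s=%r for missing input", score, name, value)
        else:
            raise MissingInputError(score, name)
    return value


def avpu_from_gcs(gcs: int) -> Avpu:
    """Map a Glasgow Coma Scale value onto the AVPU scale.

    Conventional correspondence: 14-15 Alert, 9-13 responds to Voice,
    4-8 responds to Pain, 3 Unresponsive.  Used only when no explicit
    AVPU assessment is recorded.
    """
    if gcs != int(gcs) or not 3 <= gcs <= 15:
        raise ValueError(f"gcs must be an integer in [3, 15], got {gcs!r}")
    gcs = int(gcs)
    if gcs >= 14:
        return Avpu.ALERT
    if gcs >= 9:
        return Avpu.VOICE
    if gcs >= 4:
        return Avpu.PAIN
    return Avpu.UNRESPONSIVE


def raps_score(vitals: Vitals, *, impute_normal: bool = False) -> ScoreBreakdown:
    """Rapid Acute Physiology Score from pulse rate, MAP, RR and GCS (0-16)."""
    pr = round_half_up(_require("RAPS", vitals, "pulse_rate", impute_normal))
    mapr = round_half_up(_require("RAPS", vitals, "mean_arterial_pressure", impute_normal))
    rr = round_half_up(_require("RAPS", vitals, "respiratory_rate", impute_normal))
    gcs = _require("RAPS", vitals, "gcs", impute_normal)
    components = {
        "pulse_rate": _lookup(_RAPS_PR, pr),
        "mean_arterial_pressure": _lookup(_RAPS_MAP, mapr),
        "respiratory_rate": _lookup(_RAPS_RR, rr),
        "gcs": _lookup(_GCS_BANDS, gcs),
    }
    return ScoreBreakdown("RAPS", sum(components.values()), components)


def rems_score(vitals: Vitals, age: float, *, impute_normal: bool = False) -> ScoreBreakdown:
    """Rapid Emergency Medicine Score: RAPS variables plus age and SpO2 (0-26)."""
    if age is None:
        raise MissingInputError("REMS", "age")
    base = raps_score(vitals, impute_normal=impute_normal)
    spo2 = round_half_up(_require("REMS", vitals, "spo2", impute_normal))
    components = {"age": _lookup(_REMS_AGE, round_half_up(age))}
    components.update(base.components)
    components["spo2"] = _lookup(_REMS_SPO2, spo2)
    return ScoreBreakdown("REMS", sum(components.values()), components)


def mews_score(vitals: Vitals, *, impute_normal: bool = False) -> ScoreBreakdown:
    """Modified Early Warning Score from SBP, heart rate, RR, temperature and AVPU (0-14).

    Heart rate is taken from ``pulse_rate``.  If no AVPU assessment is
    recorded it is derived from GCS; an explicit AVPU takes precedence.
    """
    sbp = round_half_up(_require("MEWS", vitals, "systolic_bp", impute_normal))
    hr = round_half_up(_require("MEWS", vitals, "pulse_rate", impute_normal))
    rr = round_half_up(_require("MEWS", vitals, "respiratory_rate", impute_normal))
    temp = round_half_up(_require("MEWS", vitals, "temperature", impute_normal), 1)
    avpu = vitals.avpu
    if avpu is None:
        if vitals.gcs is not None:
            avpu = avpu_from_gcs(vitals.gcs)
        elif impute_normal:
            avpu = _NORMAL_VALUES["avpu"]
            logger.info("MEWS: imputing normal avpu=%r for missing input", avpu)
        else:
            raise MissingInputError("MEWS", "avpu")
    components = {
        "systolic_bp": _lookup(_MEWS_SBP, sbp),
        "heart_rate": _lookup(_MEWS_HR, hr),
        "respiratory_rate": _lookup(_MEWS_RR, rr),
        "temperature": _lookup(_MEWS_TEMP10, int(round(temp * 10))),
        "avpu": _MEWS_AVPU[Avpu(avpu)],
    }
    return ScoreBreakdown("MEWS", sum(components.values()), components)


def tachypnea_or_hypoxia(vitals: Vitals, oxygen_by_mask: bool) -> bool:
    """MEDS respiratory criterion: RR > 20/min, or oxygen by mask, or SpO2 < 90%.

    Inequalities are strict, so RR = 20 with SpO2 = 90 and no mask does
    not qualify.
    """
    if oxygen_by_mask:
        return True
    if vitals.respiratory_rate is None:
        raise MissingInputError("MEDS", "respiratory_rate")
    if vitals.respiratory_rate > 20:
        return True
    if vitals.spo2 is None:
        raise MissingInputError("MEDS", "spo2")
    return vitals.spo2 < 90


def meds_score(vitals: Vitals, criteria: MedsCriteria) -> ScoreBreakdown:
    """Mortality in Emergency Department Sepsis score (0-27).

    Nine weighted criteria: terminal illness 6; age > 65, tachypnea or
    hypoxia, septic shock, platelets < 150e9/L, bands > 5% each 3;
    lower respiratory infection, nursing home residency, altered mental
    status each 2.
    """
    if criteria.platelet_count is None:
        raise MissingInputError("MEDS", "platelet_count")
    if criteria.band_percent is None:
        raise MissingInputError("MEDS", "band_percent")
    ams = criteria.altered_mental_status
    if ams is None:
        if vitals.gcs is None:
            raise MissingInputError("MEDS", "altered_mental_status")
        ams = vitals.gcs <= 13
    components = {
        "terminal_illness": 6 if criteria.terminal_illness else 0,
        "age_gt_65": 3 if criteria.age > 65 else 0,
        "tachypnea_or_hypoxia": 3 if tachypnea_or_hypoxia(vitals, criteria.oxygen_by_mask) else 0,
        "septic_shock": 3 if criteria.septic_shock else 0,
        "platelets_lt_150": 3 if criteria.platelet_count < 150 else 0,
        "bands_gt_5pct": 3 if criteria.band_percent > 5 else 0,
        "lower_respiratory_infection": 2 if criteria.lower_respiratory_infection else 0,
        "nursing_home_resident": 2 if criteria.nursing_home_resident else 0,
        "altered_mental_status": 2 if ams else 0,
    }
    return ScoreBreakdown("MEDS", sum(components.values()), components)
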