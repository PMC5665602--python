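"""Seeded synthetic splenic-abscess cohort generator.

No patient-level data is published for the 114-patient multicenter ED
splenic-abscess cohort that motivates this package, only arm-wise
summary statistics: medians with interquartile ranges for the
continuous variables and frequencies for the categorical ones, reported
separately for the 100 survivors and 14 non-survivors.  This module
turns those summaries into a fully specified sampling model so that the
whole scoring-and-evaluation pipeline is testable end to end.

Model
-----
* Each continuous variable is drawn from a log-normal distribution
  whose parameters are fitted to the published median and IQR
  (:func:`fit_lognormal_to_median_iqr`), truncated by rejection to a
  physiological range.  Log-normals have positive support and the right
  skew typical of vitals and lab counts.
* Categorical variables and boolean flags are count-calibrated: each
  category's count in an arm is fixed at the largest-remainder rounding
  of n * probability and the labels are randomly permuted across the
  arm's patients.  A generated arm therefore reproduces the published
  group frequencies essentially exactly at every seed (a resample of
  the observed margins), rather than merely in expectation.
* Variables are independent within an arm: the source reports no
  correlation structure, so independence is the honest default (and a
  documented limitation — real vitals are correlated).
* GCS is drawn in two stages: a published band (<=8, 9-11, >=12), then
  an integer within the band; within >=12 the mass is concentrated on
  15 (0.80) as most ward-admitted patients are fully alert.
* SpO2 and systolic BP are not reported; defaults are SpO2 ~
  normal(97, 2) in survivors and (93, 4) in non-survivors clipped to
  [50, 100], and SBP = MAP + (2/3) * 40 mmHg (a fixed pulse pressure of
  40 mmHg).  Both are overridable in the spec.
* MEDS-only flags not reported (nursing-home residency, lower
  respiratory infection, bands > 5%, oxygen by mask) default to
  probabilities (0.05, 0.10, 0.15, 0.05) in survivors and double in
  non-survivors; these values are synthetic conventions, not published
  facts.

Generation is deterministic given ``CohortSpec.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import yaml
from scipy.stats import norm

from .cohort import Cohort, PatientRecord
from .scoring import MedsCriteria, Vitals, avpu_from_gcs

__all__ = [
    "MedianIqr",
    "LognormalFit",
    "ArmSpec",
    "CohortSpec",
    "fit_lognormal_to_median_iqr",
    "default_cohort_spec",
    "generate",
    "spec_to_yaml",
    "spec_from_yaml",
]

_Z75 = norm.ppf(0.75)  # ~0.6744897501960817

#: Physiological truncation bounds per continuous variable (rejection sampling).
PHYSIOLOGICAL_BOUNDS = {
    "age": (18.0, 100.0),
    "pulse_rate": (20.0, 250.0),
    "respiratory_rate": (4.0, 80.0),
    "mean_arterial_pressure": (20.0, 250.0),
    "temperature": (30.0, 43.0),
    "platelet_count": (1.0, 1500.0),  # 1e9/L
    "leukocyte_count": (100.0, 200000.0),  # per microliter
}


class MedianIqr(NamedTuple):
    """A published summary: median with (q1, q3) interquartile bounds."""

    median: float
    q1: float
    q3: float


class LognormalFit(NamedTuple):
    """Log-normal parameters fitted to a median/IQR summary.

    ``residual`` is the root-sum-square misfit of the log 25th/75th
    percentiles; zero when the IQR is symmetric on the log scale.
    """

    mu: float
    sigma: float
    residual: float


def fit_lognormal_to_median_iqr(median: float, q1: float, q3: float) -> LognormalFit:
    """Fit a log-normal to a (median, q1, q3) summary.

    The median is matched exactly (mu = ln median).  sigma is the least
    squares solution for the two log-quantile equations
    ``mu -/+ z75 * sigma = ln q1 / ln q3``, i.e.
    ``sigma = ln(q3/q1) / (2 * z75)`` with z75 the standard normal 75th
    percentile.  A log-symmetric IQR is reproduced exactly (residual 0);
    otherwise the residual quantifies the asymmetry the two-parameter
    family cannot express.
    """
    if not (0 < q1 < median < q3):
        raise ValueError(
            f"quantiles must satisfy 0 < q1 < median < q3, got q1={q1!r}, median={median!r}, q3={q3!r}"
        )
    mu = math.log(median)
    sigma = math.log(q3 / q1) / (2 * _Z75)
    r1 = mu - _Z75 * sigma - math.log(q1)
    r3 = mu + _Z75 * sigma - math.log(q3)
    return LognormalFit(mu, sigma, math.hypot(r1, r3))


@dataclass(frozen=True)
class ArmSpec:
    """Sampling targets for one outcome arm (survivors or non-survivors).

    ``continuous`` maps variable name -> MedianIqr; ``binary`` maps flag
    name -> probability of True; ``categorical`` maps variable name ->
    {category: probability}.  ``spo2`` is (mean, sd) of a clipped normal.
    """

    n: int
    continuous: dict[str, MedianIqr]
    binary: dict[str, float]
    categorical: dict[str, dict[str, float]]
    spo2: tuple[float, float]
    pulse_pressure: float = 40.0  # mmHg; SBP = MAP + 2/3 * pulse_pressure
    gcs_within_high: dict[int, float] = field(
        default_factory=lambda: {12: 0.05, 13: 0.05, 14: 0.10, 15: 0.80}
    )

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("arm size must be non-negative")
        for name, t in self.continuous.items():
            if not (0 < t.q1 < t.median < t.q3):
                raise ValueError(f"{name}: need 0 < q1 < median < q3, got {t}")
        for name, p in self.binary.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{name}: probability {p!r} outside [0, 1]")
        for name, probs in self.categorical.items():
            if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1) > 1e-9:
                raise ValueError(f"{name}: category probabilities must be >= 0 and sum to 1")


@dataclass(frozen=True)
class CohortSpec:
    """Two-arm cohort recipe; the default composition is 100 survivors / 14 non-survivors."""

    survivor_arm: ArmSpec
    nonsurvivor_arm: ArmSpec
    seed: int = 0


def default_cohort_spec(seed: int = 0, scale: int = 1) -> CohortSpec:
    """The packaged spec encoding the published splenic-abscess cohort summaries.

    Arm sizes are 100 survivors and 14 non-survivors, multiplied by
    ``scale`` for large-sample checks.  Continuous targets are the
    published per-arm median (IQR) values; categorical probabilities are
    the published frequencies (count-based where the printed percentage
    disagrees with the printed count, e.g. non-survivor septic shock is
    6/14).  Platelets are in 1e9/L, leukocytes per microliter.
    """
    survivor = ArmSpec(
        n=100 * scale,
        continuous={
            "age": MedianIqr(55.5, 42, 71),
            "temperature": MedianIqr(38, 36.9, 39),
            "pulse_rate": MedianIqr(106, 88, 117.5),
            "respiratory_rate": MedianIqr(20, 19, 20.5),
            "mean_arterial_pressure": MedianIqr(94, 75.5, 112),
            "leukocyte_count": MedianIqr(13000, 8950, 18550),
            "platelet_count": MedianIqr(221, 152, 303.5),
        },
        binary={
            "male": 0.70,
            "septic_shock": 0.04,
            "terminal_illness": 0.01,
            "nursing_home_resident": 0.05,
            "lower_respiratory_infection": 0.10,
            "bands_gt_5pct": 0.15,
            "oxygen_by_mask": 0.05,
        },
        categorical={
            "gcs_band": {"le8": 0.01, "9_11": 0.01, "ge12": 0.98},
            "etiology": {
                "hematogenous": 0.62,
                "sickle_cell_related": 0.08,
                "traumatic": 0.11,
                "contiguous": 0.19,
            },
            "abscess_multiplicity": {"solitary": 0.74, "multiple": 0.26},
            "treatment": {"conservative": 0.49, "aspiration": 0.24, "operation": 0.27},
        },
        spo2=(97.0, 2.0),
    )
    nonsurvivor = ArmSpec(
        n=14 * scale,
        continuous={
            "age": MedianIqr(55, 52, 78),
            "temperature": MedianIqr(38, 37, 39),
            "pulse_rate": MedianIqr(120.5, 108, 142),
            "respiratory_rate": MedianIqr(22, 20, 27),
            "mean_arterial_pressure": MedianIqr(72.5, 59, 98),
            "leukocyte_count": MedianIqr(13500, 6900, 20500),
            "platelet_count": MedianIqr(162.5, 41, 224),
        },
        binary={
            "male": 0.50,
            "septic_shock": 6 / 14,
            "terminal_illness": 1 / 14,
            "nursing_home_resident": 0.10,
            "lower_respiratory_infection": 0.20,
            "bands_gt_5pct": 0.30,
            "oxygen_by_mask": 0.10,
        },
        categorical={
            "gcs_band": {"le8": 2 / 14, "9_11": 2 / 14, "ge12": 10 / 14},
            "etiology": {
                "hematogenous": 10 / 14,
                "sickle_cell_related": 4 / 14,
                "traumatic": 0.0,
                "contiguous": 0.0,
            },
            "abscess_multiplicity": {"solitary": 6 / 14, "multiple": 8 / 14},
            "treatment": {"conservative": 9 / 14, "aspiration": 2 / 14, "operation": 3 / 14},
        },
        spo2=(93.0, 4.0),
    )
    return CohortSpec(survivor_arm=survivor, nonsurvivor_arm=nonsurvivor, seed=seed)


def _sample_truncated_lognormal(
    rng: np.random.Generator, target: MedianIqr, bounds: tuple[float, float], n: int
) -> np.ndarray:
    """Truncated log-normal sample preserving the target median.

    Truncation is symmetric in probability: whichever physiological
    bound cuts the larger tail mass, the same mass is removed from the
    other tail, so the median of the truncated distribution equals the
    fitted (target) median exactly.  The effective bounds are at least
    as tight as the physiological ones.
    """
    fit = fit_lognormal_to_median_iqr(*target)
    lo, hi = bounds
    z_lo = (math.log(lo) - fit.mu) / fit.sigma
    z_hi = (math.log(hi) - fit.mu) / fit.sigma
    alpha = max(norm.cdf(z_lo), norm.sf(z_hi))
    if alpha >= 0.5:
        raise ValueError(f"target {target} incompatible with physiological bounds {bounds}")
    z_cut = norm.ppf(1 - alpha) if alpha > 0 else math.inf
    out = rng.normal(fit.mu, fit.sigma, size=n)
    for _ in range(1000):
        bad = np.abs(out - fit.mu) > z_cut * fit.sigma
        if not bad.any():
            return np.exp(out)
        out[bad] = rng.normal(fit.mu, fit.sigma, size=int(bad.sum()))
    raise RuntimeError(f"rejection sampling failed to stay within {bounds} for target {target}")


def _largest_remainder_counts(probs: dict, n: int) -> dict:
    """Integer category counts summing to n, by largest-remainder rounding of n*p."""
    exact = {k: n * p for k, p in probs.items()}
    counts = {k: int(math.floor(v)) for k, v in exact.items()}
    short = n - sum(counts.values())
    by_frac = sorted(probs, key=lambda k: (-(exact[k] - counts[k]), str(k)))
    for k in by_frac[:short]:
        counts[k] += 1
    return counts


def _permuted_labels(rng: np.random.Generator, probs: dict, n: int) -> np.ndarray:
    """A random permutation of the count-calibrated label multiset."""
    counts = _largest_remainder_counts(probs, n)
    labels = np.concatenate([np.repeat(k, c) for k, c in counts.items()]) if n else np.array([])
    return labels[rng.permutation(n)]


def _sample_gcs(rng: np.random.Generator, arm: ArmSpec, n: int) -> np.ndarray:
    bands = _permuted_labels(rng, arm.categorical["gcs_band"], n)
    gcs = np.empty(n, dtype=int)
    high_vals = np.array(sorted(arm.gcs_within_high))
    high_p = np.array([arm.gcs_within_high[v] for v in high_vals], dtype=float)
    high_p = high_p / high_p.sum()
    for i, band in enumerate(bands):
        if band == "le8":
            gcs[i] = rng.integers(3, 9)
        elif band == "9_11":
            gcs[i] = rng.integers(9, 12)
        else:
            gcs[i] = rng.choice(high_vals, p=high_p)
    return gcs


def _generate_arm(rng: np.random.Generator, arm: ArmSpec, outcome: str, id_prefix: str) -> list[PatientRecord]:
    n = arm.n
    cont = {
        name: _sample_truncated_lognormal(rng, target, PHYSIOLOGICAL_BOUNDS[name], n)
        for name, target in sorted(arm.continuous.items())
    }
    flags = {
        name: _permuted_labels(rng, {True: p, False: 1 - p}, n).astype(bool)
        for name, p in sorted(arm.binary.items())
    }
    gcs = _sample_gcs(rng, arm, n)
    spo2 = np.clip(rng.normal(arm.spo2[0], arm.spo2[1], size=n), 50.0, 100.0)
    cats = {
        name: _permuted_labels(rng, probs, n)
        for name, probs in sorted(arm.categorical.items())
        if name != "gcs_band"
    }
    band_pct = np.where(flags["bands_gt_5pct"], rng.uniform(6, 15, size=n), rng.uniform(0, 5, size=n))

    records = []
    for i in range(n):
        g = int(gcs[i])
        mapr = float(np.round(cont["mean_arterial_pressure"][i], 1))
        vitals = Vitals(
            pulse_rate=float(np.round(cont["pulse_rate"][i], 1)),
            respiratory_rate=float(np.round(cont["respiratory_rate"][i], 1)),
            systolic_bp=float(np.round(mapr + 2 / 3 * arm.pulse_pressure, 1)),
            mean_arterial_pressure=mapr,
            temperature=float(np.round(cont["temperature"][i], 1)),
            spo2=float(np.round(spo2[i], 1)),
            gcs=g,
            avpu=avpu_from_gcs(g),
        )
        meds = MedsCriteria(
            age=float(np.round(cont["age"][i], 1)),
            terminal_illness=bool(flags["terminal_illness"][i]),
            septic_shock=bool(flags["septic_shock"][i]),
            platelet_count=float(np.round(cont["platelet_count"][i], 1)),
            band_percent=float(np.round(band_pct[i], 1)),
            lower_respiratory_infection=bool(flags["lower_respiratory_infection"][i]),
            nursing_home_resident=bool(flags["nursing_home_resident"][i]),
            altered_mental_status=g <= 13,
            oxygen_by_mask=bool(flags["oxygen_by_mask"][i]),
        )
        records.append(
            PatientRecord(
                patient_id=f"{id_prefix}{i + 1:05d}",
                vitals=vitals,
                meds_criteria=meds,
                sex="male" if flags["male"][i] else "female",
                leukocyte_count=float(np.round(cont["leukocyte_count"][i])),
                etiology=cats["etiology"][i],
                abscess_multiplicity=cats["abscess_multiplicity"][i],
                treatment=cats["treatment"][i],
                outcome=outcome,
            )
        )
    return records


def generate(spec: CohortSpec) -> Cohort:
    """Draw a synthetic cohort from ``spec``, deterministically in ``spec.seed``.

    Survivor records come first (ids S#####), then non-survivors
    (ids D#####); arm sizes are exact.
    """
    rng = np.random.default_rng(spec.seed)
    records = _generate_arm(rng, spec.survivor_arm, "survived", "S")
    records += _generate_arm(rng, spec.nonsurvivor_arm, "died", "D")
    return Cohort(records=records, provenance="synthetic", seed=spec.seed)


# ---------------------------------------------------------------------------
# Plain-text (YAML) spec serialization for the command line.


def spec_to_yaml(spec: CohortSpec) -> str:
    def arm(a: ArmSpec) -> dict:
        return {
            "n": a.n,
            "continuous": {k: {"median": t.median, "q1": t.q1, "q3": t.q3} for k, t in a.continuous.items()},
            "binary": dict(a.binary),
            "categorical": {k: dict(v) for k, v in a.categorical.items()},
            "spo2": {"mean": a.spo2[0], "sd": a.spo2[1]},
            "pulse_pressure": a.pulse_pressure,
        }

    return yaml.safe_dump(
        {"seed": spec.seed, "survivor_arm": arm(spec.survivor_arm), "nonsurvivor_arm": arm(spec.nonsurvivor_arm)},
        sort_keys=False,
    )


def spec_from_yaml(text: str) -> CohortSpec:
    raw = yaml.safe_load(text)

    def arm(d: dict) -> ArmSpec:
        return ArmSpec(
            n=int(d["n"]),
            continuous={k: MedianIqr(v["median"], v["q1"], v["q3"]) for k, v in d["continuous"].items()},
            binary={k: float(v) for k, v in d["binary"].items()},
            categorical={k: {c: float(p) for c, p in v.items()} for k, v in d["categorical"].items()},
            spo2=(float(d["spo2"]["mean"]), float(d["spo2"]["sd"])),
            pulse_pressure=float(d.get("pulse_pressure", 40.0)),
        )

    return CohortSpec(
        survivor_arm=arm(raw["survivor_arm"]),
        nonsurvivor_arm=arm(raw["nonsurvivor_arm"]),
        seed=int(raw.get("seed", 0)),
    )
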