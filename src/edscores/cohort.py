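"""Patient-cohort data model, CSV input/output and validation.

A cohort is an ordered collection of :class:`PatientRecord` objects, one
per ED patient, holding triage vitals, MEDS risk criteria, etiology /
abscess-multiplicity / treatment categories and the hospital outcome
(survived or died).  The CSV serialization is comma-separated UTF-8 with
"." decimals, lowercase ``true``/``false`` booleans and empty cells for
missing values; :func:`write_cohort` followed by :func:`read_cohort` is
the identity at the record level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .scoring import Avpu, MedsCriteria, Vitals

__all__ = [
    "ETIOLOGIES",
    "TREATMENTS",
    "MULTIPLICITIES",
    "OUTCOMES",
    "SEXES",
    "COLUMNS",
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
]

ETIOLOGIES = ("hematogenous", "sickle_cell_related", "traumatic", "contiguous")
TREATMENTS = ("conservative", "aspiration", "operation")
MULTIPLICITIES = ("solitary", "multiple")
OUTCOMES = ("survived", "died")
SEXES = ("male", "female")

#: Canonical CSV column order.
COLUMNS = (
    "patient_id",
    "sex",
    "age",
    "pulse_rate",
    "respiratory_rate",
    "systolic_bp",
    "mean_arterial_pressure",
    "temperature",
    "spo2",
    "gcs",
    "avpu",
    "leukocyte_count",
    "platelet_count",
    "band_percent",
    "terminal_illness",
    "septic_shock",
    "lower_respiratory_infection",
    "nursing_home_resident",
    "altered_mental_status",
    "oxygen_by_mask",
    "etiology",
    "abscess_multiplicity",
    "treatment",
    "outcome",
)


class CohortValidationError(ValueError):
    """Carries every offending (row, column, message) cell of a bad cohort file.

    Row numbers are 1-based data rows (the header is row 0).
    """

    def __init__(self, problems: Sequence[tuple[int, str, str]]):
        self.problems = list(problems)
        lines = [f"  row {r}, column '{c}': {m}" for r, c, m in self.problems]
        super().__init__("cohort validation failed:\n" + "\n".join(lines))


@dataclass
class PatientRecord:
    """One ED patient: vitals, MEDS criteria, clinical categories, outcome."""

    patient_id: str
    vitals: Vitals
    meds_criteria: MedsCriteria
    sex: str | None = None
    leukocyte_count: float | None = None  # cells per microliter
    etiology: str | None = None
    abscess_multiplicity: str | None = None
    treatment: str | None = None
    outcome: str | None = None

    @property
    def age(self) -> float:
        return self.meds_criteria.age


@dataclass
class Cohort:
    """An ordered patient collection with provenance and (optional) seed."""

    records: list[PatientRecord] = field(default_factory=list)
    provenance: str = "observed"  # "observed" or "synthetic"
    seed: int | None = None

    def __post_init__(self):
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_died(self) -> int:
        return sum(r.outcome == "died" for r in self.records)

    @property
    def n_survived(self) -> int:
        return sum(r.outcome == "survived" for r in self.records)

    def outcomes(self) -> list[int]:
        """0/1 outcome labels (1 = died), requiring every record labelled."""
        out = []
        for r in self.records:
            if r.outcome not in OUTCOMES:
                raise ValueError(f"patient {r.patient_id} has no outcome label")
            out.append(int(r.outcome == "died"))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a DataFrame in the canonical column order."""
        rows = [_record_to_row(r) for r in self.records]
        return pd.DataFrame(rows, columns=list(COLUMNS))


def _record_to_row(r: PatientRecord) -> dict:
    v, m = r.vitals, r.meds_criteria
    return {
        "patient_id": r.patient_id,
        "sex": r.sex,
        "age": m.age,
        "pulse_rate": v.pulse_rate,
        "respiratory_rate": v.respiratory_rate,
        "systolic_bp": v.systolic_bp,
        "mean_arterial_pressure": v.mean_arterial_pressure,
        "temperature": v.temperature,
        "spo2": v.spo2,
        "gcs": v.gcs,
        "avpu": v.avpu.value if v.avpu is not None else None,
        "leukocyte_count": r.leukocyte_count,
        "platelet_count": m.platelet_count,
        "band_percent": m.band_percent,
        "terminal_illness": m.terminal_illness,
        "septic_shock": m.septic_shock,
        "lower_respiratory_infection": m.lower_respiratory_infection,
        "nursing_home_resident": m.nursing_home_resident,
        "altered_mental_status": m.altered_mental_status,
        "oxygen_by_mask": m.oxygen_by_mask,
        "etiology": r.etiology,
        "abscess_multiplicity": r.abscess_multiplicity,
        "treatment": r.treatment,
        "outcome": r.outcome,
    }


def _parse_float(cell: str, lo: float = -math.inf, hi: float = math.inf):
    if cell == "":
        return None
    x = float(cell)
    if not math.isfinite(x) or not lo <= x <= hi:
        raise ValueError(f"value {cell!r} outside [{lo}, {hi}]")
    return x


def _parse_bool(cell: str):
    if cell == "":
        return None
    if cell not in ("true", "false"):
        raise ValueError(f"expected 'true' or 'false', got {cell!r}")
    return cell == "true"


def _parse_enum(cell: str, allowed: tuple):
    if cell == "":
        return None
    if cell not in allowed:
        raise ValueError(f"unknown label {cell!r}; allowed: {', '.join(allowed)}")
    return cell


def _row_to_record(row: Mapping[str, str]) -> PatientRecord:
    """Parse one CSV row (strings, '' = missing) into a PatientRecord.

    Raises ValueError with the offending column name prefixed.
    """

    def get(col, parser, *args):
        try:
            return parser(row.get(col, ""), *args)
        except ValueError as exc:
            raise ValueError(f"{col}\t{exc}") from None

    gcs = get("gcs", _parse_float, 3, 15)
    if gcs is not None:
        if gcs != int(gcs):
            raise ValueError(f"gcs\tmust be an integer, got {gcs!r}")
        gcs = int(gcs)
    avpu_raw = get("avpu", _parse_enum, tuple(a.value for a in Avpu))
    try:
        vitals = Vitals(
            pulse_rate=get("pulse_rate", _parse_float, 0, math.inf),
            respiratory_rate=get("respiratory_rate", _parse_float, 0, math.inf),
            systolic_bp=get("systolic_bp", _parse_float, 0, math.inf),
            mean_arterial_pressure=get("mean_arterial_pressure", _parse_float, 0, math.inf),
            temperature=get("temperature", _parse_float),
            spo2=get("spo2", _parse_float, 0, 100),
            gcs=gcs,
            avpu=Avpu(avpu_raw) if avpu_raw is not None else None,
        )
    except ValueError as exc:
        msg = str(exc)
        if "\t" not in msg:
            msg = f"vitals\t{msg}"
        raise ValueError(msg) from None
    age = get("age", _parse_float, 18, math.inf)
    if age is None:
        raise ValueError("age\tage is required")
    meds = MedsCriteria(
        age=age,
        terminal_illness=get("terminal_illness", _parse_bool) or False,
        septic_shock=get("septic_shock", _parse_bool) or False,
        platelet_count=get("platelet_count", _parse_float, 0, math.inf),
        band_percent=get("band_percent", _parse_float, 0, 100),
        lower_respiratory_infection=get("lower_respiratory_infection", _parse_bool) or False,
        nursing_home_resident=get("nursing_home_resident", _parse_bool) or False,
        altered_mental_status=get("altered_mental_status", _parse_bool),
        oxygen_by_mask=get("oxygen_by_mask", _parse_bool) or False,
    )
    pid = row.get("patient_id", "")
    if pid == "":
        raise ValueError("patient_id\tpatient_id is required")
    return PatientRecord(
        patient_id=pid,
        vitals=vitals,
        meds_criteria=meds,
        sex=get("sex", _parse_enum, SEXES),
        leukocyte_count=get("leukocyte_count", _parse_float, 0, math.inf),
        etiology=get("etiology", _parse_enum, ETIOLOGIES),
        abscess_multiplicity=get("abscess_multiplicity", _parse_enum, MULTIPLICITIES),
        treatment=get("treatment", _parse_enum, TREATMENTS),
        outcome=get("outcome", _parse_enum, OUTCOMES),
    )


def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None) -> Cohort:
    """Read a patient cohort from CSV, validating every cell.

    Parameters
    ----------
    path
        CSV file with a header row; one data row per patient.
    schema
        Optional mapping from file column names to canonical names, for
        files using different headers.

    Leading ``#`` comment lines are skipped; ``seed=`` and
    ``provenance=`` tokens in them (as written by :func:`write_cohort`)
    are recovered onto the returned cohort.

    Raises
    ------
    CohortValidationError
        listing every offending row/column, including duplicate ids.
    """
    provenance, seed = "observed", None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line.lstrip("#").split():
                if token.startswith("seed="):
                    seed = int(token.removeprefix("seed="))
                elif token.startswith("provenance="):
                    provenance = token.removeprefix("provenance=")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    if schema:
        df = df.rename(columns=dict(schema))
    problems: list[tuple[int, str, str]] = []
    records: list[PatientRecord] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        try:
            rec = _row_to_record(row)
        except ValueError as exc:
            col, _, msg = str(exc).partition("\t")
            problems.append((i, col, msg or col))
            continue
        if rec.patient_id in seen:
            problems.append((i, "patient_id", f"duplicate id {rec.patient_id!r} (first seen row {seen[rec.patient_id]})"))
            continue
        seen[rec.patient_id] = i
        records.append(rec)
    if problems:
        raise CohortValidationError(problems)
    return Cohort(records=records, provenance=provenance, seed=seed)


def _format_cell(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if isinstance(x, bool):
        return "true" if x else "false"
    if isinstance(x, float):
        return repr(x) if x != int(x) else str(int(x))
    s = str(x)
    if any(ch in s for ch in ',"\n'):
        s = '"' + s.replace('"', '""') + '"'
    return s


def write_cohort(cohort: Cohort, path: str | Path, header_comments: Iterable[str] = ()) -> None:
    """Write a cohort to CSV, re-readable by :func:`read_cohort` without loss.

    ``header_comments`` are emitted as leading ``#`` lines (provenance,
    seed, package version); :func:`read_cohort` skips them.
    """
    path = Path(path)
    lines = [f"# {c}" for c in header_comments]
    lines.append(",".join(COLUMNS))
    for rec in cohort.records:
        row = _record_to_row(rec)
        lines.append(",".join(_format_cell(row[c]) for c in COLUMNS))
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"failed writing cohort to {path}: {exc}") from exc
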