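"""Patient record domain types, validation and CSV/JSON serialization.

A cohort is a flat table: one row per patient, sixteen self-reported risk
items plus the ancillary items needed for the modified STOP-BANG, modified
Lee (RCRI), modified Apfel and APAIS scores, and an optional 6-month
complication outcome. Missing answers are explicit (``None`` in memory,
empty cell in CSV, ``null`` in JSON) and are never imputed at I/O time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Optional

import pandas as pd

SCHEMA_VERSION = 1

#: The 16 stratification items, in questionnaire order.
RISK_ITEMS = (
    "age",
    "bmi",
    "drug_allergy",
    "hemostasis_disorder",
    "n_medications",
    "active_smoking",
    "asthma",
    "sleep_apnea",
    "max_activity",
    "cardiac_symptoms_exercise",
    "hypertension",
    "cardiac_disease",
    "respiratory_disease",
    "renal_disease",
    "neuro_disorder",
    "diabetes",
)

#: Ancillary self-report items feeding the derived scores (not part of the
#: 16-item stratification rule).
ANCILLARY_ITEMS = (
    "sex",
    "snoring",
    "daytime_tiredness",
    "observed_apnea",
    "history_ponv_or_motion_sickness",
    "insulin_use",
    "ischemic_heart_disease",
    "heart_failure",
    "cerebrovascular_disease",
    "apais_1",
    "apais_2",
    "apais_3",
    "apais_4",
    "apais_5",
    "apais_6",
)

APAIS_FIELDS = tuple(f"apais_{i}" for i in range(1, 7))

BOOL_FIELDS = frozenset(
    {
        "drug_allergy",
        "hemostasis_disorder",
        "active_smoking",
        "asthma",
        "sleep_apnea",
        "cardiac_symptoms_exercise",
        "hypertension",
        "cardiac_disease",
        "respiratory_disease",
        "renal_disease",
        "neuro_disorder",
        "diabetes",
        "snoring",
        "daytime_tiredness",
        "observed_apnea",
        "history_ponv_or_motion_sickness",
        "insulin_use",
        "ischemic_heart_disease",
        "heart_failure",
        "cerebrovascular_disease",
    }
)


class Stratum(str, Enum):
    """Risk stratum color label, ordered green < orange < red.

    ``modified_green``/``modified_red`` are reassignments of orange
    (intermediate-risk) patients by the classifier; they are never applied
    to patients whose original label was green or red.
    """

    GREEN = "green"
    ORANGE = "orange"
    RED = "red"
    MODIFIED_GREEN = "modified_green"
    MODIFIED_RED = "modified_red"

    @property
    def base_order(self) -> int:
        if self in (Stratum.GREEN, Stratum.MODIFIED_GREEN):
            return 0
        if self is Stratum.ORANGE:
            return 1
        return 2


@dataclass
class PatientRecord:
    """One patient's raw self-reported answers; any field may be None."""

    patient_id: str
    age: Optional[int] = None
    bmi: Optional[float] = None
    drug_allergy: Optional[bool] = None
    hemostasis_disorder: Optional[bool] = None
    n_medications: Optional[int] = None
    active_smoking: Optional[bool] = None
    asthma: Optional[bool] = None
    sleep_apnea: Optional[bool] = None
    max_activity: Optional[str] = None  # "full" | "limited"
    cardiac_symptoms_exercise: Optional[bool] = None
    hypertension: Optional[bool] = None
    cardiac_disease: Optional[bool] = None
    respiratory_disease: Optional[bool] = None
    renal_disease: Optional[bool] = None
    neuro_disorder: Optional[bool] = None
    diabetes: Optional[bool] = None
    sex: Optional[str] = None  # "male" | "female"
    snoring: Optional[bool] = None
    daytime_tiredness: Optional[bool] = None
    observed_apnea: Optional[bool] = None
    history_ponv_or_motion_sickness: Optional[bool] = None
    insulin_use: Optional[bool] = None
    ischemic_heart_disease: Optional[bool] = None
    heart_failure: Optional[bool] = None
    cerebrovascular_disease: Optional[bool] = None
    apais_1: Optional[int] = None
    apais_2: Optional[int] = None
    apais_3: Optional[int] = None
    apais_4: Optional[int] = None
    apais_5: Optional[int] = None
    apais_6: Optional[int] = None


@dataclass
class Outcome:
    """Six-month composite complication outcome for one patient."""

    patient_id: str
    complication: Optional[bool] = None
    event_types: Optional[tuple[str, ...]] = None


@dataclass
class Violation:
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule}"


def validate_record(record: PatientRecord) -> list[Violation]:
    """Check a record's invariants; violations are returned, never raised."""
    out: list[Violation] = []
    if not record.patient_id:
        out.append(Violation("patient_id", "must be a non-empty string"))
    if record.age is not None and record.age < 18:
        out.append(Violation("age", "must be >= 18 years"))
    if record.bmi is not None and not (10 < record.bmi < 80):
        out.append(Violation("bmi", "must lie in (10, 80) kg/m^2"))
    if record.n_medications is not None and record.n_medications < 0:
        out.append(Violation("n_medications", "must be >= 0"))
    if record.max_activity is not None and record.max_activity not in ("full", "limited"):
        out.append(Violation("max_activity", "must be 'full' or 'limited'"))
    if record.sex is not None and record.sex not in ("male", "female"):
        out.append(Violation("sex", "must be 'male' or 'female'"))
    for name in APAIS_FIELDS:
        v = getattr(record, name)
        if v is not None and not (1 <= v <= 5):
            out.append(Violation(name, "Likert item must lie in [1, 5]"))
    return out


def validate_outcome(outcome: Outcome) -> list[Violation]:
    out: list[Violation] = []
    if outcome.event_types is not None and outcome.complication is not None:
        if bool(outcome.event_types) != outcome.complication:
            out.append(
                Violation("event_types", "complication must be yes iff event_types nonempty")
            )
    return out


# ---------------------------------------------------------------------------
# serialization

_RECORD_FIELDS = [f.name for f in dataclasses.fields(PatientRecord)]
COHORT_COLUMNS = _RECORD_FIELDS + ["complication", "event_types"]

_INT_FIELDS = frozenset({"age", "n_medications", *APAIS_FIELDS})


def _to_cell(name: str, value: Any) -> Any:
    if value is None:
        return ""
    if name in BOOL_FIELDS or name == "complication":
        return "yes" if value else "no"
    if name == "event_types":
        return ";".join(value)
    return value


def _from_cell(name: str, value: Any) -> Any:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if name in BOOL_FIELDS or name == "complication":
        if isinstance(value, bool):
            return value
        s = str(value).strip().lower()
        if s in ("yes", "true", "1"):
            return True
        if s in ("no", "false", "0"):
            return False
        raise ValueError(f"column {name!r}: cannot parse boolean from {value!r}")
    if name == "event_types":
        if isinstance(value, (list, tuple)):
            return tuple(value)
        return tuple(s for s in str(value).split(";") if s)
    if name in _INT_FIELDS:
        return int(value)
    if name == "bmi":
        return float(value)
    return str(value)


def cohort_to_frame(
    records: list[PatientRecord], outcomes: Optional[list[Outcome]] = None
) -> pd.DataFrame:
    """Serialize a cohort to a flat table (strings, yes/no booleans)."""
    by_id = {o.patient_id: o for o in (outcomes or [])}
    rows = []
    for r in records:
        row = {name: _to_cell(name, getattr(r, name)) for name in _RECORD_FIELDS}
        o = by_id.get(r.patient_id)
        row["complication"] = _to_cell("complication", o.complication if o else None)
        row["event_types"] = _to_cell("event_types", o.event_types) if o and o.event_types else ""
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(df: pd.DataFrame) -> tuple[list[PatientRecord], list[Outcome]]:
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise ValueError(f"unknown column(s): {', '.join(unknown)}")
    if "patient_id" not in df.columns:
        raise ValueError("missing required column 'patient_id'")
    records, outcomes = [], []
    for _, row in df.iterrows():
        kwargs = {
            name: _from_cell(name, row[name]) for name in _RECORD_FIELDS if name in df.columns
        }
        records.append(PatientRecord(**kwargs))
        comp = _from_cell("complication", row["complication"]) if "complication" in df.columns else None
        ev = _from_cell("event_types", row["event_types"]) if "event_types" in df.columns else None
        if comp is not None or ev is not None:
            outcomes.append(Outcome(patient_id=kwargs["patient_id"], complication=comp, event_types=ev))
    return records, outcomes


def write_cohort(
    path: str | Path,
    records: list[PatientRecord],
    outcomes: Optional[list[Outcome]] = None,
    format: Optional[str] = None,
) -> None:
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    df = cohort_to_frame(records, outcomes)
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# myrisk-cohort-schema: {SCHEMA_VERSION}\n")
            df.to_csv(fh, index=False)
    elif fmt == "json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "patients": [
                {k: (None if v == "" else v) for k, v in row.items()}
                for row in df.to_dict(orient="records")
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_cohort(
    path: str | Path, format: Optional[str] = None
) -> tuple[list[PatientRecord], list[Outcome]]:
    """Read a cohort file; missing cells become None, file order is kept."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("json" if path.suffix == ".json" else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    elif fmt == "json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["patients"])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return frame_to_cohort(df)
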