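"""Deterministic risk scoring.

Each of the 16 self-reported items maps to an independent level (1, 2 or 3);
the global stratum follows a three-rule cascade:

* green  — all 16 items at level 1 (low risk);
* red    — at least one level-3 item, or at least three level-2 items
  (high risk; takes precedence over orange);
* orange — otherwise, i.e. one or two level-2 items and no level-3
  (intermediate risk).

Also computes the ancillary self-report scores: modified STOP-BANG (7 of the
8 obstructive-sleep-apnea screen items; neck circumference is not
self-reportable and is excluded), modified Lee/RCRI (4 cardiac-risk
comorbidities), modified Apfel (3 PONV risk factors) and the APAIS
anesthesia-anxiety subscale (3 Likert items, range 3-15).

Numeric cut points: interval bounds written as ranges ("65 to 80",
"30 to 40", "1 to 5") are closed — age 65 and 80 are both level 2 —
matching the complementary strict bounds of levels 1 and 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .records import RISK_ITEMS, PatientRecord, Stratum

#: Admissible levels per criterion. Two-row criteria never emit the absent
#: level: asthma-like items have no level 3; activity and exercise cardiac
#: symptoms have no level 2.
ADMISSIBLE_LEVELS: dict[str, tuple[int, ...]] = {
    "age": (1, 2, 3),
    "bmi": (1, 2, 3),
    "drug_allergy": (1, 2),
    "hemostasis_disorder": (1, 2),
    "n_medications": (1, 2, 3),
    "active_smoking": (1, 2),
    "asthma": (1, 2),
    "sleep_apnea": (1, 2),
    "max_activity": (1, 3),
    "cardiac_symptoms_exercise": (1, 3),
    "hypertension": (1, 2),
    "cardiac_disease": (1, 2),
    "respiratory_disease": (1, 2),
    "renal_disease": (1, 2),
    "neuro_disorder": (1, 2),
    "diabetes": (1, 2),
}

MISSING_POLICIES = ("error", "escalate_to_level2", "treat_as_level1")


@dataclass(frozen=True)
class ItemAssessment:
    criterion: str
    level: int
    missing: bool = False

    def __post_init__(self) -> None:
        if self.criterion not in ADMISSIBLE_LEVELS:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.level not in ADMISSIBLE_LEVELS[self.criterion]:
            raise ValueError(
                f"level {self.level} not admissible for {self.criterion!r} "
                f"(admits {ADMISSIBLE_LEVELS[self.criterion]})"
            )


@dataclass(frozen=True)
class MyRiskResult:
    patient_id: str
    assessments: tuple[ItemAssessment, ...]
    n_level2: int
    n_level3: int
    stratum: Stratum

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(a.level for a in self.assessments)


def _require_bool(criterion: str, value) -> bool:
    if not isinstance(value, bool):
        raise TypeError(f"{criterion}: expected yes/no, got {value!r}")
    return value


def assess_item(criterion: str, raw_value) -> ItemAssessment:
    """Map one raw answer to its risk level.

    Raises on unknown criteria or type-mismatched values; missing values
    (None) are returned flagged at level 1 — the caller's missing policy
    decides what to do with them.
    """
    if criterion not in ADMISSIBLE_LEVELS:
        raise ValueError(f"unknown criterion {criterion!r}")
    if raw_value is None:
        return ItemAssessment(criterion, 1, missing=True)
    if criterion == "age":
        age = int(raw_value)
        level = 1 if age < 65 else (2 if age <= 80 else 3)
    elif criterion == "bmi":
        bmi = float(raw_value)
        level = 1 if bmi < 30 else (2 if bmi <= 40 else 3)
    elif criterion == "n_medications":
        n = int(raw_value)
        if n < 0:
            raise ValueError("n_medications must be >= 0")
        level = 1 if n == 0 else (2 if n <= 5 else 3)
    elif criterion == "max_activity":
        if raw_value not in ("full", "limited"):
            raise TypeError(f"max_activity: expected 'full'/'limited', got {raw_value!r}")
        level = 1 if raw_value == "full" else 3
    elif criterion == "cardiac_symptoms_exercise":
        level = 3 if _require_bool(criterion, raw_value) else 1
    else:  # plain yes/no items: yes -> level 2
        level = 2 if _require_bool(criterion, raw_value) else 1
    return ItemAssessment(criterion, level)


def stratum_from_counts(n_level2: int, n_level3: int) -> Stratum:
    """Stratum from the level-2/level-3 counts alone (the cascade's core)."""
    if n_level3 >= 1 or n_level2 >= 3:
        return Stratum.RED
    if n_level2 >= 1:
        return Stratum.ORANGE
    return Stratum.GREEN


def compute_myrisk(
    record: PatientRecord, missing_policy: str = "escalate_to_level2"
) -> MyRiskResult:
    """Assess all 16 items and classify the patient.

    missing_policy:
      * ``error`` — raise on any missing item;
      * ``escalate_to_level2`` — a missing answer takes the lowest
        admissible elevated level (2, or 3 for the two items without a
        level 2): missing information raises risk, never lowers it;
      * ``treat_as_level1`` — missing answers count as unremarkable.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    assessments = []
    for criterion in RISK_ITEMS:
        a = assess_item(criterion, getattr(record, criterion))
        if a.missing:
            if missing_policy == "error":
                raise ValueError(f"missing item {criterion!r} for {record.patient_id!r}")
            if missing_policy == "escalate_to_level2":
                elevated = min(l for l in ADMISSIBLE_LEVELS[criterion] if l > 1)
                a = ItemAssessment(criterion, elevated, missing=True)
        assessments.append(a)
    n2 = sum(1 for a in assessments if a.level == 2)
    n3 = sum(1 for a in assessments if a.level == 3)
    return MyRiskResult(
        patient_id=record.patient_id,
        assessments=tuple(assessments),
        n_level2=n2,
        n_level3=n3,
        stratum=stratum_from_counts(n2, n3),
    )


# ---------------------------------------------------------------------------
# ancillary scores

#: Default component items for each derived score. The instruments'
#: self-report adaptations are not standardized item-by-item, so these sets
#: are configuration with documented defaults, not hard-coded rules.
STOPBANG_ITEMS_DEFAULT = (
    "snoring",
    "daytime_tiredness",
    "observed_apnea",
    "hypertension",
    "bmi_gt_35",
    "age_gt_50",
    "male_sex",
)
LEE_ITEMS_DEFAULT = (
    "ischemic_heart_disease",
    "heart_failure",
    "cerebrovascular_disease",
    "insulin_treated_diabetes",
)
APFEL_ITEMS_DEFAULT = ("female_sex", "nonsmoker", "history_ponv_or_motion_sickness")
APAIS_ANESTHESIA_ITEMS_DEFAULT = (1, 2, 3)


def _component_value(record: PatientRecord, item: str) -> Optional[bool]:
    """Resolve a score component, including the derived pseudo-items."""
    if item == "bmi_gt_35":
        return None if record.bmi is None else record.bmi > 35
    if item == "age_gt_50":
        return None if record.age is None else record.age > 50
    if item == "male_sex":
        return None if record.sex is None else record.sex == "male"
    if item == "female_sex":
        return None if record.sex is None else record.sex == "female"
    if item == "nonsmoker":
        return None if record.active_smoking is None else not record.active_smoking
    if item == "insulin_treated_diabetes":
        if record.diabetes is False:
            return False
        if record.insulin_use is None or record.diabetes is None:
            return None
        return record.diabetes and record.insulin_use
    return getattr(record, item)


def _count_positives(
    record: PatientRecord, items: Sequence[str], missing_policy: str, score_name: str
) -> int:
    total = 0
    for item in items:
        v = _component_value(record, item)
        if v is None:
            if missing_policy == "error":
                raise ValueError(f"missing {score_name} component {item!r}")
            v = False  # treat_as_negative
        total += int(v)
    return total


def compute_stopbang_modified(
    record: PatientRecord,
    items: Sequence[str] = STOPBANG_ITEMS_DEFAULT,
    missing_policy: str = "treat_as_negative",
) -> int:
    """Modified STOP-BANG: count of positives among the 7 collected items."""
    return _count_positives(record, items, missing_policy, "STOP-BANG")


def compute_lee_modified(
    record: PatientRecord,
    items: Sequence[str] = LEE_ITEMS_DEFAULT,
    missing_policy: str = "treat_as_negative",
) -> int:
    """Modified Lee/RCRI: count of positive cardiac-risk comorbidities (0-4)."""
    return _count_positives(record, items, missing_policy, "Lee")


def compute_apfel_modified(
    record: PatientRecord,
    items: Sequence[str] = APFEL_ITEMS_DEFAULT,
    missing_policy: str = "treat_as_negative",
) -> int:
    """Modified Apfel PONV score: count of positive risk factors (0-3)."""
    return _count_positives(record, items, missing_policy, "Apfel")


def compute_apais_anesthesia(
    record: PatientRecord,
    items: Sequence[int] = APAIS_ANESTHESIA_ITEMS_DEFAULT,
    missing_policy: str = "error",
) -> Optional[int]:
    """APAIS anesthesia-anxiety subscale: sum of 3 Likert items (3-15).

    With missing_policy='skip', returns None when any component is missing.
    """
    values = [getattr(record, f"apais_{i}") for i in items]
    if any(v is None for v in values):
        if missing_policy == "error":
            raise ValueError(f"missing APAIS item(s) for {record.patient_id!r}")
        return None
    return int(sum(values))
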