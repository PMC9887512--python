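import numpy as np
import pytest

from myrisk.records import Outcome, PatientRecord


def make_record(pid: str = "p1", **overrides) -> PatientRecord:
    """A fully observed, all-clear (green) patient; override fields to taste."""
    base = dict(
        patient_id=pid,
        age=39,
        bmi=25.0,
        drug_allergy=False,
        hemostasis_disorder=False,
        n_medications=0,
        active_smoking=False,
        asthma=False,
        sleep_apnea=False,
        max_activity="full",
        cardiac_symptoms_exercise=False,
        hypertension=False,
        cardiac_disease=False,
        respiratory_disease=False,
        renal_disease=False,
        neuro_disorder=False,
        diabetes=False,
        sex="male",
        snoring=False,
        daytime_tiredness=False,
        observed_apnea=False,
        history_ponv_or_motion_sickness=False,
        insulin_use=False,
        ischemic_heart_disease=False,
        heart_failure=False,
        cerebrovascular_disease=False,
        apais_1=1,
        apais_2=2,
        apais_3=3,
        apais_4=1,
        apais_5=1,
        apais_6=2,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def green_record() -> PatientRecord:
    return make_record()


@pytest.fixture
def small_cohort() -> tuple[list[PatientRecord], list[Outcome]]:
    records = [
        make_record("a"),
        make_record("b", age=70, hypertension=True, bmi=None),
        make_record("c", cardiac_symptoms_exercise=True, n_medications=7),
    ]
    outcomes = [
        Outcome("a", complication=False),
        Outcome("b", complication=False),
        Outcome("c", complication=True, event_types=("rehospitalization",)),
    ]
    return records, outcomes
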