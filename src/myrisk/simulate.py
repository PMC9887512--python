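"""Synthetic patient cohort generator.

No individual-level data accompany the study this package operationalizes,
so every downstream stage is exercised on simulated cohorts built to carry
the published statistical structure: stratum mix 25.7% green / 38.6% orange
/ 35.7% red, stratum-conditional 6-month complication rates 0/100, 4/150
and 12/139, age median 39 (IQR 27-54), 60.1% male, BMI mean 25 (SD 4).

Sampling is constructive (stratum-first): each patient's stratum is drawn
first, then a 16-item level vector is drawn from the finite set of vectors
admissible for that stratum (enumerated once and cached), then levels are
back-mapped to raw answers. By construction, re-scoring a generated record
recovers its target stratum exactly — the generator is an inverse of the
scoring rule.

An optional planted signal (``signal_strength`` > 0) tilts both the level
vectors and the outcome probabilities toward a designated set of
informative items, giving the feature-selection and reclassification
stages a recoverable ground truth. At strength 0 (default) sampling is
exactly uniform over each stratum's admissible set and outcomes depend on
the stratum alone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from .records import RISK_ITEMS, Outcome, PatientRecord
from .scoring import ADMISSIBLE_LEVELS, stratum_from_counts
from .records import Stratum

#: Items carrying the planted signal when signal_strength > 0.
DESIGNATED_SIGNAL_ITEMS = (
    "hypertension",
    "cardiac_disease",
    "respiratory_disease",
    "diabetes",
)

STRATA = (Stratum.GREEN, Stratum.ORANGE, Stratum.RED)


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic cohort."""

    n_patients: int = 1000
    stratum_probs: tuple[float, float, float] = (0.257, 0.386, 0.357)
    complication_prob_by_stratum: tuple[float, float, float] = (
        0.0,
        4 / 150,
        12 / 139,
    )
    age_quartiles: tuple[float, float, float] = (27.0, 39.0, 54.0)
    male_frac: float = 0.601
    bmi_mean_sd: tuple[float, float] = (25.0, 4.0)
    missing_frac: Mapping[str, float] = field(default_factory=dict)
    signal_strength: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        p = np.asarray(self.stratum_probs, dtype=float)
        if p.shape != (3,) or (p < 0).any() or (p > 1).any() or abs(p.sum() - 1) > 1e-9:
            raise ValueError("stratum_probs must be a 3-vector in [0,1] summing to 1")
        q = np.asarray(self.complication_prob_by_stratum, dtype=float)
        if q.shape != (3,) or (q < 0).any() or (q > 1).any():
            raise ValueError("complication_prob_by_stratum must be a 3-vector in [0,1]")
        if not (18 <= self.age_quartiles[0] <= self.age_quartiles[1] <= self.age_quartiles[2] < 65):
            raise ValueError("age_quartiles must be nondecreasing within [18, 65)")
        for name, frac in self.missing_frac.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"missing_frac[{name!r}] must lie in [0,1]")


@lru_cache(maxsize=1)
def _admissible_space() -> dict:
    """Enumerate all admissible 16-item level vectors, grouped by stratum.

    The space is small (3^3 * 2^13 * ... = 221,184 vectors) and is built
    once per process.
    """
    per_item = [ADMISSIBLE_LEVELS[c] for c in RISK_ITEMS]
    vectors = np.array(list(itertools.product(*per_item)), dtype=np.int8)
    n2 = (vectors == 2).sum(axis=1)
    n3 = (vectors == 3).sum(axis=1)
    strata = np.where(
        (n3 >= 1) | (n2 >= 3), 2, np.where(n2 >= 1, 1, 0)
    )  # 0=green, 1=orange, 2=red
    designated_idx = [RISK_ITEMS.index(c) for c in DESIGNATED_SIGNAL_ITEMS]
    d = (vectors[:, designated_idx] >= 2).sum(axis=1)
    return {
        "vectors": vectors,
        "stratum_code": strata,
        "d": d,
        "by_stratum": {s: np.flatnonzero(strata == s) for s in (0, 1, 2)},
    }


def _sample_level_vectors(
    rng: np.random.Generator, stratum_codes: np.ndarray, signal_strength: float
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one admissible level vector per patient, conditional on stratum."""
    space = _admissible_space()
    out = np.empty((len(stratum_codes), len(RISK_ITEMS)), dtype=np.int8)
    d_out = np.empty(len(stratum_codes), dtype=np.int64)
    for s in (0, 1, 2):
        mask = stratum_codes == s
        if not mask.any():
            continue
        pool = space["by_stratum"][s]
        if signal_strength == 0.0:
            picks = rng.choice(pool, size=mask.sum(), replace=True)
        else:
            w = np.exp(signal_strength * space["d"][pool].astype(float))
            picks = rng.choice(pool, size=mask.sum(), replace=True, p=w / w.sum())
        out[mask] = space["vectors"][picks]
        d_out[mask] = space["d"][picks]
    return out, d_out


def _piecewise_uniform_age(
    rng: np.random.Generator, n: int, quartiles: tuple[float, float, float]
) -> np.ndarray:
    """Ages <65 with the configured quartiles: four equal-mass uniform bands."""
    q1, q2, q3 = quartiles
    edges = np.array([18.0, q1, q2, q3, 65.0])
    band = rng.integers(0, 4, size=n)
    u = rng.uniform(size=n)
    lo, hi = edges[band], edges[band + 1]
    return np.floor(lo + u * (hi - lo)).astype(int).clip(18, 64)


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    # simple rejection; acceptance is near 1 for the default (25, 4) on (10, 30)
    out = rng.normal(mean, sd, size=n)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


_LIKERT_P = np.array([0.35, 0.25, 0.20, 0.12, 0.08])


def _backmap_records(
    rng: np.random.Generator, levels: np.ndarray, config: CohortConfig
) -> list[PatientRecord]:
    """Translate level vectors into raw questionnaire answers."""
    n = levels.shape[0]
    col = {c: levels[:, i] for i, c in enumerate(RISK_ITEMS)}
    mean, sd = config.bmi_mean_sd

    age = np.where(
        col["age"] == 1,
        _piecewise_uniform_age(rng, n, config.age_quartiles),
        np.where(
            col["age"] == 2,
            rng.integers(65, 81, size=n),
            rng.integers(81, 96, size=n),
        ),
    )
    # bands pulled in by 0.05 so rounding to 1 decimal cannot cross a cut point
    bmi = np.where(
        col["bmi"] == 1,
        _truncated_normal(rng, n, mean, sd, 10.05, 29.95),
        np.where(
            col["bmi"] == 2,
            rng.uniform(30.0, 40.0, size=n),
            rng.uniform(40.05, 60.0, size=n),
        ),
    )
    n_meds = np.where(
        col["n_medications"] == 1,
        0,
        np.where(
            col["n_medications"] == 2,
            rng.integers(1, 6, size=n),
            rng.integers(6, 11, size=n),
        ),
    )

    male = rng.uniform(size=n) < config.male_frac
    sleep_apnea = col["sleep_apnea"] == 2
    snoring = rng.uniform(size=n) < np.where(sleep_apnea, 0.75, 0.25)
    tired = rng.uniform(size=n) < np.where(sleep_apnea, 0.55, 0.20)
    observed = rng.uniform(size=n) < np.where(sleep_apnea, 0.60, 0.03)
    ponv = rng.uniform(size=n) < 0.20
    diabetes = col["diabetes"] == 2
    insulin = diabetes & (rng.uniform(size=n) < 0.30)
    cardiac = col["cardiac_disease"] == 2
    ihd = cardiac & (rng.uniform(size=n) < 0.50)
    hf = cardiac & (rng.uniform(size=n) < 0.20)
    neuro = col["neuro_disorder"] == 2
    cva = neuro & (rng.uniform(size=n) < 0.30)
    apais = rng.choice(np.arange(1, 6), size=(n, 6), p=_LIKERT_P)

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"P{i:05d}",
                age=int(age[i]),
                bmi=round(float(bmi[i]), 1),
                drug_allergy=bool(col["drug_allergy"][i] == 2),
                hemostasis_disorder=bool(col["hemostasis_disorder"][i] == 2),
                n_medications=int(n_meds[i]),
                active_smoking=bool(col["active_smoking"][i] == 2),
                asthma=bool(col["asthma"][i] == 2),
                sleep_apnea=bool(sleep_apnea[i]),
                max_activity="limited" if col["max_activity"][i] == 3 else "full",
                cardiac_symptoms_exercise=bool(col["cardiac_symptoms_exercise"][i] == 3),
                hypertension=bool(col["hypertension"][i] == 2),
                cardiac_disease=bool(cardiac[i]),
                respiratory_disease=bool(col["respiratory_disease"][i] == 2),
                renal_disease=bool(col["renal_disease"][i] == 2),
                neuro_disorder=bool(neuro[i]),
                diabetes=bool(diabetes[i]),
                sex="male" if male[i] else "female",
                snoring=bool(snoring[i]),
                daytime_tiredness=bool(tired[i]),
                observed_apnea=bool(observed[i]),
                history_ponv_or_motion_sickness=bool(ponv[i]),
                insulin_use=bool(insulin[i]),
                ischemic_heart_disease=bool(ihd[i]),
                heart_failure=bool(hf[i]),
                cerebrovascular_disease=bool(cva[i]),
                **{f"apais_{j + 1}": int(apais[i, j]) for j in range(6)},
            )
        )
    return records


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientRecord], list[Outcome], list[Stratum]]:
    """Generate a cohort; returns (records, outcomes, true_strata).

    All randomness flows from one root generator seeded with config.seed;
    the draw order (strata, level vectors, raw-value back-mapping,
    outcomes) is fixed, so identical configs give identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    codes = rng.choice(3, size=config.n_patients, p=np.asarray(config.stratum_probs))
    levels, d = _sample_level_vectors(rng, codes, config.signal_strength)
    records = _backmap_records(rng, levels, config)

    base = np.asarray(config.complication_prob_by_stratum)[codes]
    if config.signal_strength > 0:
        interior = (base > 0) & (base < 1)
        p = base.copy()
        p[interior] = expit(logit(base[interior]) + config.signal_strength * d[interior])
    else:
        p = base
    events = rng.uniform(size=config.n_patients) < p

    outcomes = [
        Outcome(patient_id=r.patient_id, complication=bool(e))
        for r, e in zip(records, events)
    ]
    true_strata = [STRATA[c] for c in codes]
    return records, outcomes, true_strata


def inject_missingness(
    records: Sequence[PatientRecord],
    missing_frac: Mapping[str, float] | float,
    seed: int = 0,
) -> list[PatientRecord]:
    """Mask fields independently at the configured per-field probability.

    ``missing_frac`` is either one rate applied to every field or a
    mapping field -> rate; patient_id is never masked. Returns new records.
    """
    import dataclasses

    field_names = [f.name for f in dataclasses.fields(PatientRecord) if f.name != "patient_id"]
    if isinstance(missing_frac, (int, float)):
        missing_frac = {name: float(missing_frac) for name in field_names}
    for name in missing_frac:
        if name == "patient_id":
            raise ValueError("patient_id cannot be masked")
        if name not in field_names:
            raise ValueError(f"unknown field {name!r}")
    rng = np.random.default_rng(seed)
    out = []
    for r in records:
        masked = {}
        for name, frac in missing_frac.items():
            if frac > 0 and rng.uniform() < frac:
                masked[name] = None
        out.append(replace(r, **masked) if masked else replace(r))
    return out
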