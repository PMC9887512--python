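"""End-to-end pipeline runner: simulate -> score -> reclassify -> evaluate.

Every stage writes a plain-text artifact (CSV/JSON) plus a provenance block
(seeds, config hash, package version) so a rerun with the same config
reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .records import Outcome, PatientRecord, Stratum, cohort_to_frame, read_cohort, write_cohort
from .reclassify import preprocess, run_reclassification
from .metrics import (
    STRATUM_ORDER,
    apply_modified_strata,
    auc_ordinal,
    confusion_from_strata,
    diagnostic_metrics,
    metrics_report,
)
from .scoring import (
    compute_apais_anesthesia,
    compute_apfel_modified,
    compute_lee_modified,
    compute_myrisk,
    compute_stopbang_modified,
)
from .simulate import CohortConfig, generate_cohort


@dataclass
class PipelineConfig:
    outdir: str = "myrisk_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_path: Optional[str] = None  # read instead of simulate when set
    missing_policy: str = "escalate_to_level2"
    stop_size: int = 25
    reclass_threshold: float = 0.5
    reclass_seed: int = 0
    evaluate: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def score_cohort(
    records: Sequence[PatientRecord],
    missing_policy: str = "escalate_to_level2",
) -> pd.DataFrame:
    """Score every record; one row per patient with levels and all scores."""
    rows = []
    for r in records:
        res = compute_myrisk(r, missing_policy=missing_policy)
        row = {"patient_id": r.patient_id}
        for a in res.assessments:
            row[f"level_{a.criterion}"] = a.level
        row["n_level2"] = res.n_level2
        row["n_level3"] = res.n_level3
        row["stratum"] = res.stratum.value
        row["stopbang_modified"] = compute_stopbang_modified(r)
        row["lee_modified"] = compute_lee_modified(r)
        row["apfel_modified"] = compute_apfel_modified(r)
        row["apais_anesthesia"] = compute_apais_anesthesia(r, missing_policy="skip")
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_strata(
    strata: dict[str, Stratum],
    outcomes: Sequence[Outcome],
    reclassification: Optional[dict[str, Stratum]] = None,
) -> dict:
    """Diagnostic report for the original (and optionally modified) score."""
    out_map = {o.patient_id: bool(o.complication) for o in outcomes if o.complication is not None}
    strata = {pid: s for pid, s in strata.items() if pid in out_map}
    report: dict = {
        "n": len(strata),
        "n_complications": int(sum(out_map[p] for p in strata)),
        "complication_rate_pct": 100 * sum(out_map[p] for p in strata) / len(strata),
    }
    counts = confusion_from_strata(strata, out_map, {Stratum.RED})
    report["original"] = metrics_report(counts, diagnostic_metrics(counts))
    scores = [STRATUM_ORDER[strata[p]] for p in strata]
    events = [out_map[p] for p in strata]
    if any(events) and not all(events):
        report["original"]["auc_ordinal"] = auc_ordinal(scores, events)
    if reclassification is not None:
        modified = apply_modified_strata(strata, {
            pid: s for pid, s in reclassification.items() if pid in strata
        })
        counts_m = confusion_from_strata(
            modified, out_map, {Stratum.RED, Stratum.MODIFIED_RED}
        )
        report["modified"] = metrics_report(counts_m, diagnostic_metrics(counts_m))
        scores_m = [STRATUM_ORDER[modified[p]] for p in modified]
        if any(events) and not all(events):
            report["modified"]["auc_ordinal"] = auc_ordinal(scores_m, events)
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order; artifacts land under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.cohort_path:
        records, outcomes = read_cohort(config.cohort_path)
        true_strata = None
    else:
        records, outcomes, true_strata = generate_cohort(config.cohort)
        write_cohort(outdir / "cohort.csv", records, outcomes)

    scored = score_cohort(records, missing_policy=config.missing_policy)
    scored.to_csv(outdir / "scored.csv", index=False)
    strata = {
        pid: Stratum(s) for pid, s in zip(scored["patient_id"], scored["stratum"])
    }

    fm = preprocess(records, outcomes, strata=strata)
    reclass, trace, _model, ml_summary = run_reclassification(
        fm,
        stop_size=config.stop_size,
        seed=config.reclass_seed,
        threshold=config.reclass_threshold,
    )
    trace.to_frame().to_csv(outdir / "rfe_trace.csv", index=False)
    pd.DataFrame(
        [(pid, label.value) for pid, label in reclass.items()],
        columns=["patient_id", "modified_stratum"],
    ).to_csv(outdir / "reclassified.csv", index=False)

    report: dict = {"ml": ml_summary}
    if config.evaluate:
        if not outcomes:
            raise ValueError("stage evaluate: no outcomes available")
        report["evaluation"] = evaluate_strata(strata, outcomes, reclass)
    if true_strata is not None:
        agree = sum(
            1 for r, t in zip(records, true_strata) if strata[r.patient_id] is t
        )
        report["generator_agreement"] = agree / len(records)

    report["provenance"] = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "cohort_seed": config.cohort.seed if not config.cohort_path else None,
        "reclass_seed": config.reclass_seed,
        "config": dataclasses.asdict(config),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
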