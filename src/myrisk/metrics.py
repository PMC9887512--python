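"""Diagnostic-performance and association statistics.

Links risk strata (original or modified) to the binary 6-month complication
outcome: 2x2 confusion counts, sensitivity/specificity/PPV/NPV, crude odds
ratio with Woolf log-scale confidence interval (Haldane-Anscombe 0.5
correction when a cell is zero), the binarized AUC (sensitivity +
specificity)/2, the ordinal Mann-Whitney AUC with ties counted one half,
and chi-square / Fisher exact association tests.

Percent rounding for comparison against published tables is half-up
(e.g. 93.75% -> 94%), not banker's rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .records import Stratum


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts; positive = high-risk label, event = complication."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    auc_binarized: Optional[float]
    or_crude: Optional[float]
    or_ci95: Optional[tuple[float, float]]
    or_corrected: bool  # Haldane-Anscombe 0.5 applied (zero cell)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.5 -> 1), as clinical tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def confusion_from_strata(
    strata: Mapping[str, Stratum],
    outcomes: Mapping[str, bool],
    positive_set: Iterable[Stratum],
) -> ConfusionCounts:
    """Cross-tabulate high-risk labels against complication outcomes.

    ``positive_set`` defines which labels count as test-positive, e.g.
    {red} for the original score or {red, modified_red} after
    reclassification.
    """
    positive = frozenset(Stratum(s) for s in positive_set)
    if not positive:
        raise ValueError("positive_set must be nonempty")
    if not strata:
        raise ValueError("empty cohort")
    if set(strata) != set(outcomes):
        missing = set(strata) ^ set(outcomes)
        raise ValueError(f"strata/outcomes patient mismatch: {sorted(missing)[:5]}")
    tp = fp = fn = tn = 0
    for pid, label in strata.items():
        pos, event = label in positive, outcomes[pid]
        if pos and event:
            tp += 1
        elif pos:
            fp += 1
        elif event:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def diagnostic_metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    """Standard 2x2 diagnostic-test metrics.

    A metric whose denominator is zero is returned as None (flagged
    undefined) rather than propagating NaN.
    """
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    ppv = _ratio(counts.tp, counts.tp + counts.fp)
    npv = _ratio(counts.tn, counts.tn + counts.fn)
    auc = (sens + spec) / 2 if sens is not None and spec is not None else None

    a, b, c, d = counts.tp, counts.fp, counts.fn, counts.tn
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_crude = (a * d) / (b * c)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    lo, hi = math.exp(math.log(or_crude) - z * se_log), math.exp(math.log(or_crude) + z * se_log)
    return DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        auc_binarized=auc,
        or_crude=or_crude,
        or_ci95=(lo, hi),
        or_corrected=corrected,
    )


def auc_ordinal(scores: Sequence[float], outcomes: Sequence[bool]) -> float:
    """Mann-Whitney concordance: P(score_event > score_nonevent) + P(tie)/2.

    Scores may be any ordered values (e.g. strata coded 0/1/2). Reduces to
    (sensitivity + specificity)/2 for binary scores.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    if scores.shape != outcomes.shape:
        raise ValueError("scores and outcomes must align")
    n1, n0 = int(outcomes.sum()), int((~outcomes).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one event and one non-event")
    ranks = stats.rankdata(scores)  # midranks handle ties
    u = ranks[outcomes].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def association_tests(table: np.ndarray | Sequence[Sequence[int]]) -> dict:
    """Pearson chi-square (no continuity correction) for an r x c table;
    adds the two-sided Fisher exact p for 2x2 tables."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a non-negative 2-D count array")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    out = {"chi2": float(chi2), "df": int(dof), "p_chi2": float(p)}
    if t.shape == (2, 2):
        out["p_fisher"] = float(stats.fisher_exact(t, alternative="two-sided")[1])
    return out


def apply_modified_strata(
    strata: Mapping[str, Stratum], reclassification: Mapping[str, Stratum]
) -> dict[str, Stratum]:
    """Replace every orange label by its modified label; green/red untouched.

    ``reclassification`` must cover exactly the orange patients and assign
    only modified_green / modified_red.
    """
    orange = {pid for pid, s in strata.items() if s is Stratum.ORANGE}
    given = set(reclassification)
    if given != orange:
        extra, missing = given - orange, orange - given
        raise ValueError(
            f"reclassification must cover exactly the orange patients "
            f"(missing {sorted(missing)[:5]}, extra {sorted(extra)[:5]})"
        )
    out = dict(strata)
    for pid, label in reclassification.items():
        if label not in (Stratum.MODIFIED_GREEN, Stratum.MODIFIED_RED):
            raise ValueError(f"{pid}: reclassified label must be modified_green/modified_red")
        out[pid] = label
    return out


# stratum ordering used when the 3-level score is treated as ordinal
STRATUM_ORDER = {
    Stratum.GREEN: 0,
    Stratum.MODIFIED_GREEN: 0,
    Stratum.ORANGE: 1,
    Stratum.RED: 2,
    Stratum.MODIFIED_RED: 2,
}


def metrics_report(
    counts: ConfusionCounts, metrics: DiagnosticMetrics
) -> dict:
    """JSON-ready report with raw and table-rounded values."""

    def pct(x: Optional[float]) -> Optional[float]:
        return None if x is None else round_half_up(100 * x)

    return {
        "counts": {"tp": counts.tp, "fp": counts.fp, "fn": counts.fn, "tn": counts.tn},
        "raw": {
            "sensitivity": metrics.sensitivity,
            "specificity": metrics.specificity,
            "ppv": metrics.ppv,
            "npv": metrics.npv,
            "auc_binarized": metrics.auc_binarized,
            "or_crude": metrics.or_crude,
            "or_ci95": list(metrics.or_ci95) if metrics.or_ci95 else None,
            "or_corrected": metrics.or_corrected,
        },
        "rounded": {
            "sensitivity_pct": pct(metrics.sensitivity),
            "specificity_pct": pct(metrics.specificity),
            "ppv_pct": pct(metrics.ppv),
            "npv_pct": pct(metrics.npv),
            "auc": None
            if metrics.auc_binarized is None
            else round_half_up(metrics.auc_binarized, 2),
        },
    }
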