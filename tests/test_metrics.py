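"""Diagnostic metrics, ordinal AUC and association tests vs brute force."""

import numpy as np
import pytest

from _oracles import (
    brute_force_auc,
    direct_metrics,
    fisher_exact_enumeration,
    textbook_chi2,
)
from myrisk.records import Stratum
from myrisk.metrics import (
    ConfusionCounts,
    apply_modified_strata,
    association_tests,
    auc_ordinal,
    confusion_from_strata,
    diagnostic_metrics,
    metrics_report,
    round_half_up,
)

# the published study's 2x2: positive = red stratum, event = complication
STUDY_COUNTS = ConfusionCounts(tp=12, fn=4, fp=127, tn=246)


def study_strata_and_outcomes():
    """Rebuild per-patient maps carrying the published stratum x outcome
    margins: green 100/0, orange 146/4, red 127/12 (no-event/event)."""
    strata, outcomes = {}, {}
    spec = [
        (Stratum.GREEN, 100, 0),
        (Stratum.ORANGE, 146, 4),
        (Stratum.RED, 127, 12),
    ]
    i = 0
    for label, n_no, n_yes in spec:
        for event in [False] * n_no + [True] * n_yes:
            strata[f"p{i}"] = label
            outcomes[f"p{i}"] = event
            i += 1
    return strata, outcomes


class TestConfusion:
    def test_study_counts_with_positive_red(self):
        strata, outcomes = study_strata_and_outcomes()
        c = confusion_from_strata(strata, outcomes, {Stratum.RED})
        assert (c.tp, c.fn, c.fp, c.tn) == (12, 4, 127, 246)
        assert c.n == 389

    def test_all_positive_degenerate(self):
        strata = {"a": Stratum.RED, "b": Stratum.RED}
        outcomes = {"a": True, "b": False}
        c = confusion_from_strata(strata, outcomes, {Stratum.RED})
        assert c.fn == c.tn == 0

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_from_strata({}, {}, {Stratum.RED})

    def test_patient_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_from_strata({"a": Stratum.RED}, {"b": True}, {Stratum.RED})

    def test_order_invariance(self):
        strata, outcomes = study_strata_and_outcomes()
        keys = list(strata)[::-1]
        c1 = confusion_from_strata(strata, outcomes, {Stratum.RED})
        c2 = confusion_from_strata(
            {k: strata[k] for k in keys}, {k: outcomes[k] for k in keys}, {Stratum.RED}
        )
        assert c1 == c2


class TestDiagnosticMetrics:
    def test_study_metrics_round_to_published_values(self):
        m = diagnostic_metrics(STUDY_COUNTS)
        assert round_half_up(100 * m.sensitivity) == 75
        assert round_half_up(100 * m.npv) == 98
        assert round_half_up(100 * m.specificity) == 66
        assert round_half_up(100 * m.ppv) == 9
        assert round_half_up(m.auc_binarized, 2) == 0.70

    def test_perfect_classifier(self):
        m = diagnostic_metrics(ConfusionCounts(tp=10, fn=0, fp=0, tn=20))
        assert m.sensitivity == m.specificity == m.ppv == m.npv == 1.0
        assert m.auc_binarized == 1.0

    def test_zero_denominators_flagged_none(self):
        m = diagnostic_metrics(ConfusionCounts(tp=0, fn=0, fp=5, tn=5))
        assert m.sensitivity is None and m.auc_binarized is None
        assert m.specificity == 0.5

    def test_zero_cell_odds_ratio_gets_haldane_correction(self):
        m = diagnostic_metrics(ConfusionCounts(tp=5, fn=0, fp=3, tn=7))
        assert m.or_corrected
        expected = (5.5 * 7.5) / (3.5 * 0.5)
        assert m.or_crude == pytest.approx(expected)
        assert m.or_ci95[0] < m.or_crude < m.or_ci95[1]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fn=0, fp=0, tn=1)

    def test_matches_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(1, 60, size=4)
            m = diagnostic_metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
            oracle = direct_metrics(int(tp), int(fp), int(fn), int(tn))
            for key in ("sensitivity", "specificity", "ppv", "npv", "auc_binarized"):
                assert getattr(m, key) == pytest.approx(oracle[key], abs=1e-12)


class TestAucOrdinal:
    def test_binary_score_equals_half_sens_plus_spec(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            scores = rng.integers(0, 2, size=40)
            events = rng.uniform(size=40) < 0.4
            if events.all() or not events.any():
                continue
            tp = int(((scores == 1) & events).sum())
            fn = int(((scores == 0) & events).sum())
            fp = int(((scores == 1) & ~events).sum())
            tn = int(((scores == 0) & ~events).sum())
            expected = (tp / (tp + fn) + tn / (tn + fp)) / 2
            assert auc_ordinal(scores, events) == pytest.approx(expected, abs=1e-12)

    def test_perfect_separation_gives_one(self):
        assert auc_ordinal([2, 2, 0, 0], [True, True, False, False]) == 1.0

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            scores = rng.integers(0, 3, size=20)
            events = rng.uniform(size=20) < 0.5
            if events.all() or not events.any():
                continue
            assert auc_ordinal(scores, events) == pytest.approx(
                brute_force_auc(scores, events), abs=1e-12
            )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc_ordinal([1, 2, 3], [True, True, True])


class TestAssociationTests:
    def test_independent_2x2_has_zero_chi2(self):
        out = association_tests([[10, 10], [10, 10]])
        assert out["chi2"] == pytest.approx(0.0)
        assert out["df"] == 1

    def test_fisher_on_perfectly_separated_table(self):
        # 2 / C(10,5) = 2/252
        out = association_tests([[5, 0], [0, 5]])
        assert out["p_fisher"] == pytest.approx(2 / 252, rel=1e-9)

    def test_chi2_matches_textbook_formula_r_by_c(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(1, 40, size=(3, 3))
            out = association_tests(t)
            stat, df, p = textbook_chi2(t)
            assert out["chi2"] == pytest.approx(stat, rel=1e-12)
            assert out["df"] == df
            assert out["p_chi2"] == pytest.approx(p, rel=1e-9)

    def test_fisher_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = rng.integers(0, 15, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            out = association_tests(t)
            assert out["p_fisher"] == pytest.approx(
                fisher_exact_enumeration(t), rel=1e-7
            )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            association_tests([[0, 0], [3, 4]])


class TestApplyModifiedStrata:
    def test_no_orange_is_identity(self):
        strata = {"a": Stratum.GREEN, "b": Stratum.RED}
        assert apply_modified_strata(strata, {}) == strata

    def test_published_reclassification_counts(self):
        strata, outcomes = study_strata_and_outcomes()
        orange_ids = [p for p, s in strata.items() if s is Stratum.ORANGE]
        no_event = [p for p in orange_ids if not outcomes[p]]
        event = [p for p in orange_ids if outcomes[p]]
        assert (len(no_event), len(event)) == (146, 4)
        reclass = {}
        for p in no_event[:65]:
            reclass[p] = Stratum.MODIFIED_RED
        for p in no_event[65:]:
            reclass[p] = Stratum.MODIFIED_GREEN
        for p in event[:3]:
            reclass[p] = Stratum.MODIFIED_RED
        reclass[event[3]] = Stratum.MODIFIED_GREEN
        modified = apply_modified_strata(strata, reclass)
        positives = {
            p for p, s in modified.items() if s in (Stratum.RED, Stratum.MODIFIED_RED)
        }
        assert len(positives) == 207
        assert sum(outcomes[p] for p in positives) == 15
        assert len(modified) == len(strata)  # count conservation

    def test_missing_orange_patient_raises(self):
        strata = {"a": Stratum.ORANGE, "b": Stratum.ORANGE}
        with pytest.raises(ValueError, match="exactly the orange"):
            apply_modified_strata(strata, {"a": Stratum.MODIFIED_RED})

    def test_extra_patient_raises(self):
        strata = {"a": Stratum.ORANGE, "b": Stratum.GREEN}
        with pytest.raises(ValueError, match="exactly the orange"):
            apply_modified_strata(
                strata,
                {"a": Stratum.MODIFIED_RED, "b": Stratum.MODIFIED_GREEN},
            )

    def test_non_modified_label_rejected(self):
        strata = {"a": Stratum.ORANGE}
        with pytest.raises(ValueError, match="modified"):
            apply_modified_strata(strata, {"a": Stratum.RED})


class TestRounding:
    @pytest.mark.parametrize(
        "x, nd, expected",
        [(93.75, 0, 94.0), (0.705, 2, 0.71), (8.5, 0, 9.0), (0.704, 2, 0.70)],
    )
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected

    def test_report_structure(self):
        rep = metrics_report(STUDY_COUNTS, diagnostic_metrics(STUDY_COUNTS))
        assert rep["rounded"]["sensitivity_pct"] == 75
        assert rep["rounded"]["auc"] == 0.70
        assert rep["counts"]["tn"] == 246
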