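"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct formulas, exhaustive
enumeration, O(n^2) pairwise scans — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import itertools
import json
import math

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom


# ---------------------------------------------------------------------------
# Shapley values of a tree ensemble, by exhaustive coalition enumeration

def _tree_expectation(tree: dict, x: np.ndarray, feat_idx: dict, S: frozenset) -> float:
    """E[f(x) | x_S] by the tree-path convention: out-of-coalition splits
    branch both ways weighted by training cover."""
    if "leaf" in tree:
        return tree["leaf"]
    f = feat_idx[tree["split"]]
    kids = {k["nodeid"]: k for k in tree["children"]}
    if f in S:
        v = x[f]
        if np.isnan(v):
            nxt = tree["missing"]
        else:
            nxt = tree["yes"] if v < tree["split_condition"] else tree["no"]
        return _tree_expectation(kids[nxt], x, feat_idx, S)
    covers = {k["nodeid"]: k["cover"] for k in tree["children"]}
    total = sum(covers.values())
    return sum(
        covers[i] / total * _tree_expectation(kids[i], x, feat_idx, S) for i in covers
    )


def brute_force_shapley(model, row) -> tuple[np.ndarray, float]:
    """Exact Shapley values over all 2^n coalitions; returns (phi, v(empty)).

    ``model`` is a fitted XGBoost classifier, ``row`` a 1-row DataFrame.
    Exponential in the number of features — use only for <= ~10 features.
    """
    booster = model.get_booster()
    feats = booster.feature_names
    feat_idx = {f: i for i, f in enumerate(feats)}
    trees = [json.loads(t) for t in booster.get_dump(with_stats=True, dump_format="json")]
    x = row.values.astype(float).ravel()
    n = len(feats)

    cache: dict[frozenset, float] = {}

    def v(S: frozenset) -> float:
        if S not in cache:
            cache[S] = sum(_tree_expectation(t, x, feat_idx, S) for t in trees)
        return cache[S]

    phi = np.zeros(n)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        for k in range(n):
            w = math.factorial(k) * math.factorial(n - k - 1) / math.factorial(n)
            for S in itertools.combinations(others, k):
                fs = frozenset(S)
                phi[i] += w * (v(fs | {i}) - v(fs))
    return phi, v(frozenset())


# ---------------------------------------------------------------------------
# diagnostic metrics, direct single-expression recomputation

def direct_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "specificity": tn / (tn + fp) if tn + fp else None,
        "ppv": tp / (tp + fp) if tp + fp else None,
        "npv": tn / (tn + fn) if tn + fn else None,
        "auc_binarized": (tp / (tp + fn) + tn / (tn + fp)) / 2
        if (tp + fn) and (tn + fp)
        else None,
    }


def brute_force_auc(scores, outcomes) -> float:
    """O(n^2) pairwise concordance with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    pos = scores[outcomes]
    neg = scores[~outcomes]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def textbook_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square by the direct sum of (O-E)^2/E."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, df, float(chi2_dist.sf(stat, df))


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    tables (same margins) no more probable than the observed one."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    p_obs = hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = hypergeom.pmf(k, n, c1, r1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)
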