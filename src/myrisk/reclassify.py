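"""Machine-learning reclassification of intermediate-risk patients.

The rule-based stratum is three-valued; the orange (intermediate) band is
clinically ambiguous. The procedure here trains a gradient-boosted tree
classifier to discriminate green from red patients, then applies it to the
orange patients and relabels each as *modified green* or *modified red*.

Stages:

1. ``preprocess`` — encode records into a numeric feature matrix
   (booleans 0/1, nominals one-hot), drop duplicate patients and features
   whose missingness exceeds a threshold, and flag orange patients for
   exclusion from training.
2. ``rfe_select`` — recursive feature elimination: repeatedly fit on a
   train split, score on a test split, and remove the feature with the
   smallest mean absolute Shapley attribution over the training rows.
3. ``train_classifier`` — grid-searched XGBoost fit on the selected
   features of the green/red patients.
4. ``reclassify_orange`` — predicted red probability >= threshold maps an
   orange patient to modified red, otherwise modified green.
5. ``attribute`` — per-patient additive feature attributions (TreeSHAP,
   margin scale) satisfying the efficiency axiom: baseline plus the sum of
   contributions equals the model's margin output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from .records import (
    ANCILLARY_ITEMS,
    APAIS_FIELDS,
    BOOL_FIELDS,
    RISK_ITEMS,
    Outcome,
    PatientRecord,
    Stratum,
)
from .scoring import compute_myrisk

NUMERIC_FIELDS = ("age", "bmi", "n_medications") + APAIS_FIELDS
NOMINAL_FIELDS = {"max_activity": ("full", "limited"), "sex": ("male", "female")}

LABEL_GREEN, LABEL_RED = 0, 1

DEFAULT_GRID = {
    "max_depth": [2, 3, 4],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [50, 100],
}


@dataclass
class FeatureMatrix:
    """Encoded per-patient features with provenance and missingness."""

    patient_ids: list[str]
    X: pd.DataFrame  # float matrix, NaN = missing
    provenance: dict[str, str]  # column -> source raw field
    missingness: dict[str, float]  # per surviving column, pre-filter fraction
    orange_mask: np.ndarray  # True where the rule-based stratum is orange
    labels: np.ndarray  # 0 green / 1 red; -1 for orange rows
    outcome: np.ndarray  # complication yes/no (False when unknown)
    dropped_columns: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class RfeStep:
    step: int
    removed: str
    train_accuracy: float
    test_accuracy: float


@dataclass
class RfeTrace:
    steps: list[RfeStep]
    selected: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.step, s.removed, s.train_accuracy, s.test_accuracy) for s in self.steps],
            columns=["step", "removed_feature", "train_accuracy", "test_accuracy"],
        )


@dataclass(frozen=True)
class AttributionVector:
    """Additive per-feature contributions for one patient (margin scale)."""

    patient_index: int
    features: tuple[str, ...]
    contributions: np.ndarray
    baseline: float
    prediction: float  # model margin output for this row

    def efficiency_gap(self) -> float:
        return float(abs(self.baseline + self.contributions.sum() - self.prediction))


def _encode(records: Sequence[PatientRecord]) -> tuple[pd.DataFrame, dict[str, str]]:
    cols: dict[str, list] = {}
    prov: dict[str, str] = {}
    for name in NUMERIC_FIELDS:
        cols[name] = [getattr(r, name) for r in records]
        prov[name] = name
    for name in sorted(BOOL_FIELDS):
        vals = [getattr(r, name) for r in records]
        cols[name] = [np.nan if v is None else float(v) for v in vals]
        prov[name] = name
    for name, levels in NOMINAL_FIELDS.items():
        vals = [getattr(r, name) for r in records]
        for lv in levels:
            col = f"{name}={lv}"
            cols[col] = [np.nan if v is None else float(v == lv) for v in vals]
            prov[col] = name
    X = pd.DataFrame(cols, dtype=float)
    return X, prov


def preprocess(
    records: Sequence[PatientRecord],
    outcomes: Optional[Sequence[Outcome]] = None,
    missing_threshold: float = 0.70,
    strata: Optional[Mapping[str, Stratum]] = None,
) -> FeatureMatrix:
    """Build the numeric feature matrix for the green/red prediction task.

    Duplicate patient_ids are dropped (first occurrence kept); columns with
    missingness strictly above ``missing_threshold`` are dropped; nominal
    fields are one-hot encoded. Orange patients are kept in the matrix but
    flagged for exclusion from training.
    """
    seen: set[str] = set()
    kept: list[PatientRecord] = []
    for r in records:
        if r.patient_id not in seen:
            seen.add(r.patient_id)
            kept.append(r)

    X, prov = _encode(kept)
    miss = X.isna().mean()
    dropped = [c for c in X.columns if miss[c] > missing_threshold]
    X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        raise ValueError("no features survive the missingness filter")

    if strata is None:
        strata = {r.patient_id: compute_myrisk(r).stratum for r in kept}
    codes = np.array(
        [
            -1
            if strata[r.patient_id] is Stratum.ORANGE
            else (LABEL_RED if strata[r.patient_id] is Stratum.RED else LABEL_GREEN)
            for r in kept
        ]
    )
    by_id = {o.patient_id: bool(o.complication) for o in (outcomes or []) if o.complication is not None}
    outcome = np.array([by_id.get(r.patient_id, False) for r in kept])
    return FeatureMatrix(
        patient_ids=[r.patient_id for r in kept],
        X=X,
        provenance={c: prov[c] for c in X.columns},
        missingness={c: float(miss[c]) for c in X.columns},
        orange_mask=codes == -1,
        labels=codes,
        outcome=outcome,
        dropped_columns=dropped,
    )


def _new_classifier(seed: int, **overrides) -> xgb.XGBClassifier:
    params = dict(
        n_estimators=50,
        max_depth=3,
        learning_rate=0.3,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        base_score=0.5,
        eval_metric="logloss",
    )
    params.update(overrides)
    return xgb.XGBClassifier(**params)


def _check_binary(y: np.ndarray) -> None:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels are degenerate: a single class was supplied")
    if not set(classes) <= {0, 1}:
        raise ValueError("labels must be coded 0 (green) / 1 (red)")


def mean_abs_attribution(model: xgb.XGBClassifier, X: pd.DataFrame) -> pd.Series:
    """Mean |Shapley contribution| per feature over the given rows."""
    dm = xgb.DMatrix(X, missing=np.nan, feature_names=list(X.columns))
    contribs = model.get_booster().predict(dm, pred_contribs=True)
    return pd.Series(np.abs(contribs[:, :-1]).mean(axis=0), index=X.columns)


def rfe_select(
    X: pd.DataFrame,
    y: np.ndarray,
    stop_size: int = 25,
    seed: int = 0,
    test_size: float = 0.2,
    clf_params: Optional[dict] = None,
) -> RfeTrace:
    """Shapley-guided recursive feature elimination.

    Each step: stratified train/test split, fit, record train/test
    accuracy, remove the feature with the smallest mean absolute
    attribution over the training rows (ties broken by column order).
    Stops when ``stop_size`` features remain.
    """
    y = np.asarray(y)
    _check_binary(y)
    if X.shape[1] < stop_size:
        raise ValueError(f"matrix has {X.shape[1]} features, fewer than stop_size={stop_size}")
    features = list(X.columns)
    steps: list[RfeStep] = []
    step = 0
    while len(features) > stop_size:
        Xtr, Xte, ytr, yte = train_test_split(
            X[features], y, test_size=test_size, stratify=y, random_state=seed + step
        )
        model = _new_classifier(seed, **(clf_params or {}))
        model.fit(Xtr, ytr)
        train_acc = float((model.predict(Xtr) == ytr).mean())
        test_acc = float((model.predict(Xte) == yte).mean())
        contrib = mean_abs_attribution(model, Xtr)
        removed = contrib.index[int(np.argmin(contrib.values))]
        features.remove(removed)
        steps.append(RfeStep(step, removed, train_acc, test_acc))
        step += 1
    return RfeTrace(steps=steps, selected=features)


def train_classifier(
    X: pd.DataFrame,
    y: np.ndarray,
    grid: Optional[dict] = None,
    seed: int = 0,
    test_size: float = 0.2,
    cv: int = 3,
) -> tuple[xgb.XGBClassifier, float, float]:
    """Grid-searched XGBoost fit; returns (model, train_acc, test_acc)."""
    y = np.asarray(y)
    _check_binary(y)
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    search = GridSearchCV(
        _new_classifier(seed),
        grid or DEFAULT_GRID,
        scoring="accuracy",
        cv=StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed),
        n_jobs=1,
        refit=True,
    )
    search.fit(Xtr, ytr)
    model = search.best_estimator_
    train_acc = float((model.predict(Xtr) == ytr).mean())
    test_acc = float((model.predict(Xte) == yte).mean())
    return model, train_acc, test_acc


def _check_features(model: xgb.XGBClassifier, X: pd.DataFrame) -> None:
    trained = model.get_booster().feature_names
    if list(X.columns) != list(trained):
        raise ValueError(
            f"feature mismatch: model was trained on {trained}, got {list(X.columns)}"
        )


def reclassify_orange(
    model: xgb.XGBClassifier,
    orange_X: pd.DataFrame,
    patient_ids: Optional[Sequence[str]] = None,
    threshold: float = 0.5,
) -> list[tuple[str, Stratum, float]]:
    """Assign each orange patient modified green or modified red.

    Returns (patient_id, modified label, predicted red probability) per
    patient; probability >= threshold maps to modified red.
    """
    if len(orange_X) == 0:
        return []
    _check_features(model, orange_X)
    ids = list(patient_ids) if patient_ids is not None else [str(i) for i in range(len(orange_X))]
    p_red = model.predict_proba(orange_X)[:, LABEL_RED]
    return [
        (pid, Stratum.MODIFIED_RED if p >= threshold else Stratum.MODIFIED_GREEN, float(p))
        for pid, p in zip(ids, p_red)
    ]


def attribute(model: xgb.XGBClassifier, row: pd.DataFrame, index: int = 0) -> AttributionVector:
    """Per-feature additive contributions for one patient (TreeSHAP).

    Contributions are on the margin (log-odds) scale; baseline +
    sum(contributions) equals the model's margin output for the row.
    """
    try:
        booster = model.get_booster()
    except Exception as exc:  # unfitted
        raise ValueError("model is not trained") from exc
    if len(row) != 1:
        row = row.iloc[[index]]
    _check_features(model, row)
    dm = xgb.DMatrix(row, missing=np.nan, feature_names=list(row.columns))
    contribs = booster.predict(dm, pred_contribs=True)[0]
    margin = float(booster.predict(dm, output_margin=True)[0])
    return AttributionVector(
        patient_index=index,
        features=tuple(row.columns),
        contributions=contribs[:-1].astype(float),
        baseline=float(contribs[-1]),
        prediction=margin,
    )


def run_reclassification(
    fm: FeatureMatrix,
    stop_size: int = 25,
    seed: int = 0,
    threshold: float = 0.5,
    grid: Optional[dict] = None,
) -> tuple[dict[str, Stratum], RfeTrace, xgb.XGBClassifier, dict]:
    """End-to-end: RFE on green/red rows, final fit, orange reclassification.

    Returns (reclassification map, RFE trace, fitted model, summary dict).
    """
    train_mask = ~fm.orange_mask
    X_train_pool = fm.X.loc[train_mask]
    y = fm.labels[train_mask]
    stop = min(stop_size, fm.X.shape[1])
    trace = rfe_select(X_train_pool, y, stop_size=stop, seed=seed)
    model, train_acc, test_acc = train_classifier(
        X_train_pool[trace.selected], y, grid=grid, seed=seed
    )
    orange_ids = [pid for pid, o in zip(fm.patient_ids, fm.orange_mask) if o]
    assignments = reclassify_orange(
        model, fm.X.loc[fm.orange_mask, trace.selected], orange_ids, threshold=threshold
    )
    reclass = {pid: label for pid, label, _ in assignments}
    summary = {
        "n_train": int(train_mask.sum()),
        "n_orange": len(orange_ids),
        "n_features_selected": len(trace.selected),
        "selected_features": list(trace.selected),
        "train_accuracy": train_acc,
        "test_accuracy": test_acc,
        "n_modified_red": sum(1 for s in reclass.values() if s is Stratum.MODIFIED_RED),
        "n_modified_green": sum(1 for s in reclass.values() if s is Stratum.MODIFIED_GREEN),
    }
    return reclass, trace, model, summary
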