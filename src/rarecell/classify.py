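"""Marker gating and the five-classifier supervised identification protocol.

Tumor cells are first defined immunologically: nucleated (DAPI+), intact,
epithelial-marker positive (CK/EpCAM) and leukocyte-marker negative
(CD45).  A supervised classifier (one of GBM, ADABOOST, SVM, RF, XGB,
each selected by 10-fold cross-validation over a small fixed grid on a
stratified 75/25 split) then scores candidates; the gate acts as a hard
veto over the machine-learning score, because the marker definition is
definitional while the classifier only narrows candidates.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .schema import FEATURE_COLUMNS, LABEL_COLUMN, POSITIVE_LABEL

__all__ = [
    "FAMILIES",
    "GateSpec",
    "ClassifierSpec",
    "EvalMetrics",
    "TrainedClassifier",
    "gate_cells",
    "split_dataset",
    "train_classifiers",
    "evaluate_classifier",
    "classify_cells",
    "roc_auc_score_ties",
]

FAMILIES: tuple[str, ...] = ("GBM", "ADABOOST", "SVM", "RF", "XGB")

#: Gate labels.
GATE_CANDIDATE = "CTC-candidate"
GATE_WBC = "WBC"
GATE_EXCLUDED = "excluded"


@dataclass(frozen=True)
class GateSpec:
    """Marker gate: fold-over-background thresholds plus intactness bounds.

    A cell is CD45-negative when its CD45 fold is at or below
    ``cd45_neg_fold`` and CD45-positive above it.
    """

    dapi_pos_fold: float = 2.0
    ck_pos_fold: float = 2.0
    cd45_neg_fold: float = 1.5
    min_solidity: float = 0.7
    min_area_um2: float = 30.0
    max_area_um2: float = 700.0

    def __post_init__(self) -> None:
        if min(self.dapi_pos_fold, self.ck_pos_fold, self.cd45_neg_fold) <= 0:
            raise ValueError("fold thresholds must be positive")


def gate_cells(table: pd.DataFrame, gate: GateSpec = GateSpec()) -> pd.Series:
    """Assign each row a gate label.

    ``CTC-candidate`` iff DAPI+ ∧ CK+ ∧ CD45− ∧ intact; ``WBC`` iff
    DAPI+ ∧ CD45+; ``excluded`` otherwise (anucleate objects, marker-
    ambiguous cells, non-intact objects).
    """
    required = ["dapi_fold", "ck_fold", "cd45_fold", "solidity", "area_um2"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    dapi_pos = table["dapi_fold"] >= gate.dapi_pos_fold
    ck_pos = table["ck_fold"] >= gate.ck_pos_fold
    cd45_pos = table["cd45_fold"] > gate.cd45_neg_fold
    intact = (
        (table["solidity"] >= gate.min_solidity)
        & (table["area_um2"] >= gate.min_area_um2)
        & (table["area_um2"] <= gate.max_area_um2)
    )
    out = pd.Series(GATE_EXCLUDED, index=table.index, name="gate_label")
    out[dapi_pos & cd45_pos] = GATE_WBC
    out[dapi_pos & ck_pos & ~cd45_pos & intact] = GATE_CANDIDATE
    return out


def split_dataset(
    table: pd.DataFrame,
    train_fraction: float = 0.75,
    seed: int = 0,
    label_col: str = LABEL_COLUMN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random train/test split (default 75/25)."""
    labels = table[label_col]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present")
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 members")
    train, test = train_test_split(
        table,
        train_size=train_fraction,
        stratify=labels,
        random_state=seed,
        shuffle=True,
    )
    return train, test


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with an optional hyperparameter-grid override."""

    family: str
    hyperparameters: Mapping[str, Sequence] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")


def _build_estimator(spec: ClassifierSpec):
    """Estimator + default CV grid for a family.

    Grids are deliberately small and fixed; the protocol compares
    families, not exhaustive tuning.
    """
    seed = spec.seed
    if spec.family == "GBM":
        est = GradientBoostingClassifier(random_state=seed)
        grid = {"n_estimators": [100], "max_depth": [2, 3]}
    elif spec.family == "ADABOOST":
        est = AdaBoostClassifier(random_state=seed)
        grid = {"n_estimators": [100, 200]}
    elif spec.family == "SVM":
        # probability outputs via Platt scaling on held-out folds
        est = Pipeline(
            [("scale", StandardScaler()),
             ("svc", CalibratedClassifierCV(
                 SVC(kernel="rbf", random_state=seed), ensemble=False, cv=3))]
        )
        grid = {"svc__estimator__C": [0.1, 1.0, 10.0]}
    elif spec.family == "RF":
        est = RandomForestClassifier(random_state=seed, n_jobs=1)
        grid = {"n_estimators": [100, 300]}
    elif spec.family == "XGB":
        est = XGBClassifier(
            random_state=seed,
            eval_metric="logloss",
            tree_method="hist",
            n_jobs=1,
        )
        grid = {"n_estimators": [100, 300], "max_depth": [2, 4]}
    else:  # pragma: no cover
        raise ValueError(spec.family)
    if spec.hyperparameters is not None:
        grid = dict(spec.hyperparameters)
    return est, grid


@dataclass
class TrainedClassifier:
    """A fitted classifier with its feature schema and CV summary."""

    family: str
    model: object
    feature_cols: tuple[str, ...]
    best_params: dict
    cv_results: pd.DataFrame
    positive_label: str = POSITIVE_LABEL

    @property
    def schema_hash(self) -> str:
        return hashlib.sha256("|".join(self.feature_cols).encode()).hexdigest()[:16]

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """P(positive class) per row."""
        missing = [c for c in self.feature_cols if c not in table.columns]
        if missing:
            raise ValueError(f"schema mismatch: missing columns {missing}")
        X = table[list(self.feature_cols)].to_numpy(dtype=float)
        return self.model.predict_proba(X)[:, 1]

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "rarecell-classifier-v1",
            "family": self.family,
            "feature_cols": list(self.feature_cols),
            "schema_hash": self.schema_hash,
            "best_params": self.best_params,
            "positive_label": self.positive_label,
            "model": self.model,
            "cv_results": self.cv_results,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        payload = joblib.load(path)
        if payload.get("format") != "rarecell-classifier-v1":
            raise ValueError("not a rarecell classifier archive")
        obj = cls(
            family=payload["family"],
            model=payload["model"],
            feature_cols=tuple(payload["feature_cols"]),
            best_params=payload["best_params"],
            cv_results=payload["cv_results"],
            positive_label=payload["positive_label"],
        )
        if obj.schema_hash != payload["schema_hash"]:
            raise ValueError("schema hash mismatch in classifier archive")
        return obj


def train_classifiers(
    train_table: pd.DataFrame,
    specs: Sequence[ClassifierSpec] | None = None,
    cv_folds: int = 10,
    label_col: str = LABEL_COLUMN,
    feature_cols: Sequence[str] | None = None,
    seed: int = 0,
) -> dict[str, TrainedClassifier]:
    """Fit classifier families with k-fold CV hyperparameter selection.

    Defaults to all five families.  Fails loudly if any class has fewer
    members than folds (which would yield degenerate single-class folds).
    """
    if specs is None:
        specs = [ClassifierSpec(f, seed=seed) for f in FAMILIES]
    if feature_cols is None:
        feature_cols = [c for c in FEATURE_COLUMNS if c in train_table.columns]
    labels = train_table[label_col]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("training data must contain both classes")
    if (counts < cv_folds).any():
        raise ValueError(
            f"a class has fewer than cv_folds={cv_folds} members; "
            "folds would be single-class"
        )
    X = train_table[list(feature_cols)].to_numpy(dtype=float)
    y = (labels == POSITIVE_LABEL).to_numpy(dtype=int)

    out: dict[str, TrainedClassifier] = {}
    for spec in specs:
        est, grid = _build_estimator(spec)
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=spec.seed)
        search = GridSearchCV(est, grid, cv=cv, scoring="roc_auc",
                              n_jobs=1, refit=True)
        search.fit(X, y)
        cv_results = pd.DataFrame(search.cv_results_)[
            ["params", "mean_test_score", "std_test_score", "rank_test_score"]
        ]
        out[spec.family] = TrainedClassifier(
            family=spec.family,
            model=search.best_estimator_,
            feature_cols=tuple(feature_cols),
            best_params=dict(search.best_params_),
            cv_results=cv_results,
        )
    return out


def roc_auc_score_ties(scores: np.ndarray, truth: np.ndarray) -> float:
    """ROC AUC as the Mann–Whitney probability with ties counted ½."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)  # midranks handle ties as 1/2
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class EvalMetrics:
    """Threshold metrics plus ROC AUC for one classifier evaluation.

    ``auc`` is ``None`` when the truth contains a single class.  Precision
    is defined as 0 when nothing is predicted positive (and F1 follows).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    tpr: float
    fpr: float
    auc: float | None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "fp", "tn", "fn", "accuracy", "precision", "recall",
                 "f1", "tpr", "fpr", "auc")}


def evaluate_classifier(
    scores: np.ndarray,
    truth: np.ndarray,
    threshold: float = 0.5,
) -> EvalMetrics:
    """Confusion-matrix metrics at a threshold plus threshold-free AUC.

    A row is predicted positive when its score is at or above the
    threshold; AUC uses all score thresholds with ties counted ½.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape or scores.size == 0:
        raise ValueError("scores and truth must be equal-length and non-empty")
    pred = scores >= threshold
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    tn = int((~pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    n = tp + fp + tn + fn
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    fpr = fp / (fp + tn) if (fp + tn) > 0 else 0.0
    try:
        auc = roc_auc_score_ties(scores, truth)
    except ValueError:
        auc = None
    return EvalMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n,
        precision=precision,
        recall=recall,
        f1=f1,
        tpr=recall,
        fpr=fpr,
        auc=auc,
    )


def five_classifier_protocol(
    table: pd.DataFrame | None = None,
    seed: int = 0,
    cv_folds: int = 10,
    threshold: float = 0.5,
) -> dict[str, EvalMetrics]:
    """Run the full supervised identification protocol and evaluate it.

    Stratified 75/25 split of a labeled feature table (the default
    synthetic table when none is given), 10-fold cross-validated training
    of all five families, and held-out evaluation of each.
    """
    if table is None:
        from .simulate import sample_feature_table

        table = sample_feature_table(n=4000, seed=seed)
    train, test = split_dataset(table, seed=seed)
    models = train_classifiers(train, cv_folds=cv_folds, seed=seed)
    truth = (test[LABEL_COLUMN] == POSITIVE_LABEL).to_numpy()
    out = {}
    for family, model in models.items():
        scores = model.predict_proba(test)
        out[family] = evaluate_classifier(scores, truth, threshold=threshold)
    return out


def classify_cells(
    model: TrainedClassifier,
    table: pd.DataFrame,
    threshold: float = 0.5,
    gate: GateSpec = GateSpec(),
    review: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score cells and apply the final decision rule with gate veto.

    The returned copy of ``table`` gains audit columns ``ctc_probability``
    and ``gate_label`` plus the decision column ``final_label`` (``CTC`` or
    ``not-CTC``).  A cell is a CTC iff its model probability is at or
    above the threshold AND its gate label is ``CTC-candidate``.

    ``review`` is the manual-confirmation hook: a frame with columns
    ``label`` (matching the table's ``label`` column, else the row index)
    and ``final_label``, whose entries override the automatic decision.
    """
    out = table.copy()
    out["ctc_probability"] = model.predict_proba(table)
    out["gate_label"] = gate_cells(table, gate)
    auto = np.where(
        (out["ctc_probability"] >= threshold) & (out["gate_label"] == GATE_CANDIDATE),
        "CTC",
        "not-CTC",
    )
    out["final_label"] = auto
    if review is not None and len(review):
        if "final_label" not in review.columns:
            raise ValueError("review table needs a final_label column")
        key = "label" if ("label" in review.columns and "label" in out.columns) \
            else None
        if key is None:
            for idx, row in review.iterrows():
                out.loc[idx, "final_label"] = row["final_label"]
        else:
            mapping = dict(zip(review["label"], review["final_label"]))
            mask = out["label"].isin(mapping)
            out.loc[mask, "final_label"] = out.loc[mask, "label"].map(mapping)
    return out
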