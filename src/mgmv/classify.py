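"""Slower/faster-progressor classification with an RBF-kernel SVM.

Patients are labeled by a median split of the 48-month change in total
motor score: label 0 (slower progressor, SP) for changes at or below the
cohort median, label 1 (faster progressor, FP) above it.  Features
(M_GMV, age, sex, baseline total) are z-standardized on the training set,
hyperparameters tuned by exhaustive grid search with 10-fold
cross-validation, and the held-out test set scored once.  The positive
class for sensitivity/specificity is SP (label 0), so

    sensitivity = TP / (TP + FN),   specificity = TN / (TN + FP),
    accuracy    = (TP + TN) / (TP + TN + FP + FN),

with TP = correctly predicted SP and TN = correctly predicted FP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ProgressionLabels", "ClassificationReport", "median_split",
    "split_train_test", "standardize", "train_svm", "evaluate",
    "DEFAULT_GRID",
]

DEFAULT_GRID = {
    "C": [0.01, 0.1, 1.0, 10.0, 100.0],
    "gamma": [1e-4, 1e-3, 1e-2, 1e-1, 1.0, "scale"],
}


@dataclass
class ProgressionLabels:
    subject_ids: list[str]
    delta_total: np.ndarray
    labels: np.ndarray          # 0 = SP (delta <= median), 1 = FP
    split_value: float

    @property
    def n_sp(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def n_fp(self) -> int:
        return int((self.labels == 1).sum())


@dataclass
class ClassificationReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    params: dict = field(default_factory=dict)
    seed: int | None = None
    sex_encoding: str = "male=1, female=0"

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc,
                "params": self.params, "seed": self.seed,
                "sex_encoding": self.sex_encoding}


def median_split(subject_ids: list[str],
                 delta_total: np.ndarray) -> ProgressionLabels:
    """Label 0 iff the change is at or below the cohort median."""
    delta_total = np.asarray(delta_total, dtype=float)
    if len(delta_total) < 2:
        raise ValueError("need at least 2 subjects for a median split")
    split = float(np.median(delta_total))
    labels = (delta_total > split).astype(int)
    return ProgressionLabels(subject_ids=list(subject_ids),
                             delta_total=delta_total, labels=labels,
                             split_value=split)


def split_train_test(n: int, test_fraction: float = 0.3,
                     seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Random unstratified partition; test size = ceil(test_fraction * n)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    train, test = train_test_split(np.arange(n), test_size=test_fraction,
                                   random_state=seed, shuffle=True)
    assert len(test) == math.ceil(test_fraction * n)
    return np.sort(train), np.sort(test)


def standardize(features: np.ndarray,
                fit_idx: np.ndarray) -> tuple[np.ndarray, StandardScaler]:
    """Z-transform all rows using mean/SD estimated on the fit rows only."""
    features = np.asarray(features, dtype=float)
    sds = features[fit_idx].std(axis=0)
    if np.any(sds == 0):
        j = int(np.flatnonzero(sds == 0)[0])
        raise ValueError(f"zero-variance feature at column {j}")
    scaler = StandardScaler().fit(features[fit_idx])
    return scaler.transform(features), scaler


def train_svm(train_features: np.ndarray, train_labels: np.ndarray,
              cv_folds: int = 10, grid: dict | None = None,
              seed: int | None = None) -> GridSearchCV:
    """Grid-search an RBF-kernel SVM by mean CV accuracy; refit on all.

    Ties in CV accuracy are broken toward the smallest C, then the smallest
    kernel width (grid order).
    """
    train_labels = np.asarray(train_labels)
    if len(set(train_labels.tolist())) < 2:
        raise ValueError("training set contains a single class")
    grid = grid or DEFAULT_GRID
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVC(kernel="rbf"), param_grid=grid, scoring="accuracy", cv=cv,
        refit=True)
    search.fit(train_features, train_labels)
    return search


def evaluate(model, test_features: np.ndarray, test_labels: np.ndarray,
             seed: int | None = None) -> ClassificationReport:
    """Confusion matrix and metrics on the held-out set, SP positive."""
    test_labels = np.asarray(test_labels)
    pred = model.predict(test_features)
    tp = int(((pred == 0) & (test_labels == 0)).sum())   # SP predicted SP
    fn = int(((pred == 1) & (test_labels == 0)).sum())   # SP predicted FP
    fp = int(((pred == 0) & (test_labels == 1)).sum())   # FP predicted SP
    tn = int(((pred == 1) & (test_labels == 1)).sum())   # FP predicted FP
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    scores = model.decision_function(test_features)
    # decision scores point toward label 1 (FP); AUC is label-symmetric
    auc = float(roc_auc_score(test_labels, scores))
    params = dict(getattr(model, "best_params_", {}))
    return ClassificationReport(tp=tp, fp=fp, fn=fn, tn=tn,
                                accuracy=accuracy, sensitivity=sensitivity,
                                specificity=specificity, auc=auc,
                                params=params, seed=seed)
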