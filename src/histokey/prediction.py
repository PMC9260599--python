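"""Slide-level response prediction from weighted cluster occupancy.

A slide's feature vector has one entry per cluster: the fraction of the
slide's QC-passed patches assigned to that cluster, multiplied by the
cluster weight W_k.  Logistic-regression and linear-SVM classifiers are
evaluated with stratified 10-fold cross-validation (per-fold accuracy,
pooled ROC/AUC from continuous scores) and optionally on a held-out
validation manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold
from sklearn.svm import SVC

from .scoring import FeatureModel

__all__ = [
    "CVResult",
    "HoldoutResult",
    "build_slide_vector",
    "build_slide_vectors",
    "make_classifier",
    "crossvalidate",
    "fit_full",
    "evaluate_holdout",
]


def build_slide_vectors(
    clusters: Sequence[int],
    slide_ids: Sequence[str],
    feature_model: FeatureModel,
) -> pd.DataFrame:
    """Per-slide W-weighted cluster-occupancy vectors.

    ``clusters[i]`` is the cluster index of patch i, ``slide_ids[i]`` its
    slide.  Rows are slides in first-appearance order; column j holds
    (fraction of the slide's patches in cluster j) * W_j.
    """
    clusters = np.asarray(clusters, dtype=int)
    slide_ids = np.asarray(slide_ids)
    if clusters.shape != slide_ids.shape:
        raise ValueError("clusters and slide_ids must have equal length")
    if len(clusters) == 0:
        raise ValueError("no patch assignments given")
    k = feature_model.k
    weights = feature_model.weights
    order = pd.unique(slide_ids)
    rows = np.zeros((len(order), k))
    for r, sid in enumerate(order):
        mask = slide_ids == sid
        n = int(mask.sum())
        if n == 0:  # pragma: no cover - unreachable via pd.unique
            raise ValueError(f"slide {sid!r} has no surviving patches")
        counts = np.bincount(clusters[mask], minlength=k)[:k]
        rows[r] = counts / n * weights
    return pd.DataFrame(rows, index=pd.Index(order, name="slide_id"))


def build_slide_vector(
    clusters: Sequence[int], feature_model: FeatureModel, slide_id: str = "slide"
) -> np.ndarray:
    """Feature vector of a single slide from its patch cluster indices."""
    if len(clusters) == 0:
        raise ValueError(f"slide {slide_id!r} has no surviving patches")
    return build_slide_vectors(clusters, [slide_id] * len(clusters), feature_model).values[0]


def make_classifier(family: str):
    if family == "logistic":
        return LogisticRegression(max_iter=1000)
    if family == "svm":
        return SVC(kernel="linear", C=1.0)
    raise ValueError(f"unknown model family {family!r}; use 'logistic' or 'svm'")


def _scores_of(clf, X, hard_labels: bool = False) -> np.ndarray:
    """Continuous ranking scores (probability / margin), or hard 0-1 labels."""
    if hard_labels:
        return clf.predict(X).astype(float)
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


@dataclass
class CVResult:
    family: str
    seed: Optional[int]
    fold_accuracies: list[float]
    auc: float                       # pooled over all out-of-fold scores
    fold_aucs: list[float]
    auc_ci: tuple[float, float]      # normal-approximation CI over folds
    roc: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    y_true: np.ndarray = field(repr=False, default=None)
    y_score: np.ndarray = field(repr=False, default=None)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def max_accuracy(self) -> float:
        return float(np.max(self.fold_accuracies))

    @property
    def min_accuracy(self) -> float:
        return float(np.min(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "seed": self.seed,
            "fold_accuracies": list(map(float, self.fold_accuracies)),
            "mean_accuracy": self.mean_accuracy,
            "max_accuracy": self.max_accuracy,
            "min_accuracy": self.min_accuracy,
            "auc": float(self.auc),
            "fold_aucs": list(map(float, self.fold_aucs)),
            "auc_ci": [float(v) for v in self.auc_ci],
        }


def crossvalidate(
    X,
    y,
    family: str = "logistic",
    n_folds: int = 10,
    seed: Optional[int] = None,
    groups: Optional[Sequence] = None,
    hard_label_roc: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of one classifier family.

    ``groups`` (e.g. patient ids) switches to group-aware stratified folds
    so that no group straddles the train/test split.  ROC/AUC default to
    continuous classifier scores; ``hard_label_roc`` uses predicted labels
    instead (the degenerate ROC some workflows report for SVMs).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("cross-validation needs both response classes present")
    if len(y) < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} labeled slides, got {len(y)}")

    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y, groups=np.asarray(groups))
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y)

    fold_acc, fold_auc = [], []
    y_true_all, y_score_all = [], []
    for train_idx, test_idx in split:
        clf = make_classifier(family)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        fold_acc.append(float(accuracy_score(y[test_idx], pred)))
        scores = _scores_of(clf, X[test_idx], hard_labels=hard_label_roc)
        y_true_all.append(y[test_idx])
        y_score_all.append(scores)
        if len(np.unique(y[test_idx])) == 2:
            fold_auc.append(float(roc_auc_score(y[test_idx], scores)))

    y_true = np.concatenate(y_true_all)
    y_score = np.concatenate(y_score_all)
    pooled_auc = float(roc_auc_score(y_true, y_score))
    fpr, tpr, _ = roc_curve(y_true, y_score)
    if fold_auc:
        mean = float(np.mean(fold_auc))
        if len(fold_auc) > 1:
            sd = float(np.std(fold_auc, ddof=1))
            half = 1.96 * sd / np.sqrt(len(fold_auc))
        else:
            half = 0.0
        ci = (max(0.0, mean - half), min(1.0, mean + half))
    else:
        ci = (pooled_auc, pooled_auc)
    return CVResult(
        family=family,
        seed=seed,
        fold_accuracies=fold_acc,
        auc=pooled_auc,
        fold_aucs=fold_auc,
        auc_ci=ci,
        roc=(fpr, tpr),
        y_true=y_true,
        y_score=y_score,
    )


def fit_full(X, y, family: str = "logistic"):
    """Fit one classifier on the entire training set (for holdout use)."""
    clf = make_classifier(family)
    clf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
    return clf


@dataclass
class HoldoutResult:
    accuracy: float
    auc: float
    roc: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"accuracy": float(self.accuracy), "auc": float(self.auc)}


def evaluate_holdout(clf, X, y, hard_label_roc: bool = False) -> HoldoutResult:
    """Evaluate a fitted classifier once on a held-out validation set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("empty validation set")
    pred = clf.predict(X)
    scores = _scores_of(clf, X, hard_labels=hard_label_roc)
    if len(np.unique(y)) == 2:
        auc = float(roc_auc_score(y, scores))
        fpr, tpr, _ = roc_curve(y, scores)
    else:
        auc, (fpr, tpr) = float("nan"), (np.array([]), np.array([]))
    return HoldoutResult(accuracy=float(accuracy_score(y, pred)), auc=auc, roc=(fpr, tpr))
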