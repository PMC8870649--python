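"""Classifier evaluation: stratified k-fold splitting, linear discriminant
scoring, empirical ROC curves with trapezoidal AUC, and Youden cut-offs.

The positive class throughout the pipeline is the non-responder (label 0):
cut-offs flag progression, and scores are oriented so that higher means
more likely non-response.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import GroupKFold, KFold, StratifiedKFold

from .selection import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "ROCResult",
    "kfold_split",
    "cross_validated_scores",
    "roc_curve",
    "youden_cutoff",
    "single_feature_roc",
]


@dataclass(frozen=True)
class CVConfig:
    k: int = 5
    seed: int = 0
    stratified: bool = True
    group_by_patient: bool = False
    discriminant: str = "linear"  # or "quadratic"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.discriminant not in ("linear", "quadratic"):
            raise ValueError(f"unknown discriminant {self.discriminant!r}")


def kfold_split(labels, cv: CVConfig, groups=None) -> np.ndarray:
    """Assign each row to one of k disjoint validation folds.

    Stratification preserves per-class proportions within one row per
    fold; identical seeds give identical folds. Raises if any training
    set would lack a class.
    """
    y = np.asarray(labels)
    n = len(y)
    if n < cv.k:
        raise ValueError(f"cannot split {n} rows into {cv.k} folds")
    if cv.group_by_patient:
        if groups is None:
            raise ValueError("group_by_patient requires groups")
        splitter = GroupKFold(n_splits=cv.k)
        iterator = splitter.split(np.zeros(n), y, groups)
    elif cv.stratified:
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
        iterator = splitter.split(np.zeros(n), y)
    else:
        splitter = KFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
        iterator = splitter.split(np.zeros(n))
    folds = np.full(n, -1, dtype=np.int64)
    classes = np.unique(y)
    for fold_id, (train_idx, val_idx) in enumerate(iterator):
        if len(np.unique(y[train_idx])) < len(classes):
            raise ValueError(f"fold {fold_id}: a class is absent from the training set")
        folds[val_idx] = fold_id
    return folds


def _make_discriminant(kind: str, regularize: bool = False):
    if kind == "quadratic":
        return QuadraticDiscriminantAnalysis(reg_param=1e-3 if regularize else 0.0)
    if regularize:
        # scaled-identity shrinkage of the pooled covariance
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-4)
    return LinearDiscriminantAnalysis(solver="svd")


def cross_validated_scores(
    table: FeatureTable, features, cv: CVConfig = CVConfig()
) -> np.ndarray:
    """Out-of-fold posterior probability of non-response for every lesion.

    A discriminant model (class-conditional Gaussians; pooled covariance
    in the linear default) is fitted on each training split and applied to
    the held-out fold, so every row is scored exactly once. A singular
    pooled covariance triggers a logged scaled-identity regularization.
    """
    features = list(features)
    missing = [f for f in features if f not in table.features.columns]
    if missing:
        raise ValueError(f"features absent from table: {missing}")
    X = table.features[features].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains missing values")
    y = table.labels.to_numpy()
    groups = None if table.patient_id is None else table.patient_id.to_numpy()
    folds = kfold_split(y, cv, groups=groups)
    scores = np.full(len(y), np.nan)
    for fold_id in range(cv.k):
        val = folds == fold_id
        train = ~val
        try:
            clf = _make_discriminant(cv.discriminant)
            clf.fit(X[train], y[train])
        except np.linalg.LinAlgError:
            logger.warning("fold %d: singular covariance, regularizing", fold_id)
            clf = _make_discriminant(cv.discriminant, regularize=True)
            clf.fit(X[train], y[train])
        class0 = int(np.flatnonzero(clf.classes_ == 0)[0])
        scores[val] = clf.predict_proba(X[val])[:, class0]
    assert np.all(np.isfinite(scores))
    return scores


@dataclass
class ROCResult:
    """Empirical ROC with trapezoidal AUC and the Youden operating point.

    ``thresholds`` are decision thresholds applied as ``score >= t`` =>
    positive; sensitivity/specificity are aligned with them. The AUC
    equals the Mann-Whitney U statistic normalized by ``n1 * n0``.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    positive_label: int = 1

    @property
    def youden_j(self) -> float:
        return self.sens_at_cutoff + self.spec_at_cutoff - 1.0


def roc_curve(scores, labels, positive_label: int = 1) -> ROCResult:
    """Empirical ROC over all distinct score thresholds.

    A case is called positive when its score is >= the threshold. Ties
    contribute half a concordant pair to the AUC (trapezoidal rule).
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    pos = y == positive_label
    n_pos = int(pos.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    pos_sorted = pos[order].astype(np.float64)
    # collapse tied scores into single thresholds
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp = np.cumsum(pos_sorted)[distinct]
    fp = (distinct + 1) - tp
    tpr = tp / n_pos
    fpr = fp / n_neg
    thresholds = s_sorted[distinct]
    auc = float(np.trapezoid(np.r_[0.0, tpr, 1.0], np.r_[0.0, fpr, 1.0]))
    sens = tpr
    spec = 1.0 - fpr
    # exact integer J-numerator avoids one-ulp cumsum noise when ranking
    # candidate cut-offs; ties go to the lowest threshold (thresholds
    # descend, so the last maximum), preferring sensitivity
    j_num = tp * n_neg - fp * n_pos
    best = len(j_num) - 1 - int(np.argmax(j_num[::-1]))
    cutoff, sens_c, spec_c = float(thresholds[best]), float(sens[best]), float(spec[best])
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_cutoff=cutoff,
        sens_at_cutoff=sens_c,
        spec_at_cutoff=spec_c,
        positive_label=positive_label,
    )


def youden_cutoff(roc: ROCResult) -> tuple[float, float, float]:
    """The threshold maximizing J = sensitivity + specificity - 1."""
    return roc.youden_cutoff, roc.sens_at_cutoff, roc.spec_at_cutoff


def single_feature_roc(values, labels, positive_label: int = 0, orient: str = "auto") -> ROCResult:
    """ROC using a raw feature as the score.

    With ``orient="auto"`` the feature sign is flipped if needed so that
    higher score implies the positive class (non-responder by default),
    matching the point-biserial direction.
    """
    x = np.asarray(values, dtype=np.float64)
    y = np.asarray(labels)
    if orient == "auto":
        pos = y == positive_label
        if x[pos].mean() < x[~pos].mean():
            x = -x
    elif orient == "flip":
        x = -x
    elif orient != "none":
        raise ValueError(f"unknown orient {orient!r}")
    return roc_curve(x, y, positive_label=positive_label)
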