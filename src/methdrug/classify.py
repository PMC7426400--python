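"""Categorical drug-response classifiers and their evaluation.

Three classifiers are trained on VSI pair features: an RBF-kernel SVM
(cost 10, gamma 0.01), a random forest and a logistic regression (both at
library defaults). Evaluation is stratified fivefold cross-validation;
each pair is scored exactly once out-of-fold, and AUPR / ROC-AUC are
reported both pooled over all out-of-fold scores and as mean +- sd across
folds. Scores are the raw continuous outputs (SVM decision values,
probability estimates for the others): only rank metrics are computed, so
no calibration is applied.

Pair-level splitting follows the original evaluation protocol but lets a
cell line appear in both training and test folds (with different drugs);
``split_by="cell"`` provides cell-disjoint folds for a leakage-free
estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .io import ValidationError
from .labeling import PairFeatures

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "CVResult",
    "IndependentTestResult",
    "make_estimator",
    "run_cv",
    "aupr",
    "auc",
    "fit_model",
    "independent_test",
]

ALGORITHMS = ("svm", "rf", "lr")


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str = "svm"
    svm_cost: float = 10.0
    svm_gamma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.svm_cost <= 0 or self.svm_gamma <= 0:
            raise ValidationError("svm cost and gamma must be > 0")


def make_estimator(spec: ModelSpec):
    if spec.algorithm == "svm":
        return SVC(C=spec.svm_cost, gamma=spec.svm_gamma, kernel="rbf", random_state=spec.seed)
    if spec.algorithm == "rf":
        return RandomForestClassifier(random_state=spec.seed)
    return LogisticRegression(max_iter=2000, random_state=spec.seed)


def _score(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "decision_function"):
        return np.asarray(estimator.decision_function(X), dtype=float)
    return np.asarray(estimator.predict_proba(X)[:, 1], dtype=float)


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValidationError("both classes must be present")


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise, non-interpolated)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(average_precision_score(labels, scores))


def auc(scores, labels) -> float:
    """ROC area: the Mann-Whitney rank statistic with ties averaged."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


@dataclass
class CVResult:
    fold_of_pair: np.ndarray  # fold index per pair
    scores: np.ndarray  # out-of-fold score per pair
    labels: np.ndarray
    aupr_folds: list[float]
    auc_folds: list[float]
    aupr_pooled: float
    auc_pooled: float
    pr_curve: tuple[np.ndarray, np.ndarray]  # (precision, recall) on pooled scores

    @property
    def aupr_mean(self) -> float:
        return float(np.mean(self.aupr_folds))

    @property
    def aupr_sd(self) -> float:
        return float(np.std(self.aupr_folds, ddof=1))

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.auc_folds))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.auc_folds, ddof=1))


def run_cv(
    features: PairFeatures,
    model: ModelSpec,
    k: int = 5,
    seed: int = 0,
    split_by: str = "pair",
) -> CVResult:
    """Stratified k-fold cross-validation; each pair scored once out-of-fold."""
    X, y = features.X, features.y
    if y is None:
        raise ValidationError("run_cv needs labeled features")
    _check_two_classes(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValidationError(f"need >= {k} pairs of each class, got {counts.tolist()}")
    if split_by == "pair":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(X, y)
    elif split_by == "cell":
        splitter = GroupKFold(n_splits=k)
        split = splitter.split(X, y, groups=np.asarray(features.cell_ids))
    else:
        raise ValidationError(f"split_by must be 'pair' or 'cell', got {split_by!r}")

    scores = np.zeros(len(y))
    fold_of_pair = np.full(len(y), -1, dtype=int)
    aupr_folds: list[float] = []
    auc_folds: list[float] = []
    for fold, (tr, te) in enumerate(split):
        est = make_estimator(model).fit(X[tr], y[tr])
        s = _score(est, X[te])
        scores[te] = s
        fold_of_pair[te] = fold
        aupr_folds.append(aupr(s, y[te]))
        auc_folds.append(auc(s, y[te]))
    assert (fold_of_pair >= 0).all(), "every pair must land in exactly one test fold"
    precision, recall, _ = precision_recall_curve(y, scores)
    return CVResult(
        fold_of_pair,
        scores,
        y.copy(),
        aupr_folds,
        auc_folds,
        aupr(scores, y),
        auc(scores, y),
        (precision, recall),
    )


def fit_model(features: PairFeatures, model: ModelSpec):
    """Fit on the full trainable pair set (for scoring an external cohort)."""
    if features.y is None:
        raise ValidationError("fit_model needs labeled features")
    _check_two_classes(features.y)
    return make_estimator(model).fit(features.X, features.y)


@dataclass
class IndependentTestResult:
    scores: np.ndarray
    pcc: float
    pcc_pvalue: float
    group_separation_p: float | None
    n_sensitive: int
    n_resistant: int


def independent_test(
    train: PairFeatures,
    model: ModelSpec,
    test: PairFeatures,
    test_response: np.ndarray,
    sensitive_mask: np.ndarray | None = None,
    resistant_mask: np.ndarray | None = None,
) -> IndependentTestResult:
    """Train on one cohort, score another, and compare to continuous responses.

    ``test_response`` is a sensitivity-oriented continuous measure (an
    active-area-style value: higher means more sensitive), aligned with the
    rows of ``test``. Reports the Pearson correlation of prediction scores
    with it and, when sensitive/resistant masks are given, a one-sided
    rank-sum test that sensitive pairs score higher.
    """
    test_response = np.asarray(test_response, dtype=float)
    if test.X.shape[1] != train.X.shape[1]:
        raise ValidationError(
            f"feature-length mismatch: train has {train.X.shape[1]}, test has {test.X.shape[1]}"
        )
    if len(test_response) != test.X.shape[0]:
        raise ValidationError("test_response length must match test pair count")
    est = fit_model(train, model)
    scores = _score(est, test.X)
    pcc, pcc_p = stats.pearsonr(scores, test_response)
    group_p = None
    n_s = n_r = 0
    if sensitive_mask is not None and resistant_mask is not None:
        sensitive_mask = np.asarray(sensitive_mask, dtype=bool)
        resistant_mask = np.asarray(resistant_mask, dtype=bool)
        n_s, n_r = int(sensitive_mask.sum()), int(resistant_mask.sum())
        if n_s and n_r:
            group_p = float(
                stats.mannwhitneyu(
                    scores[sensitive_mask], scores[resistant_mask], alternative="greater"
                ).pvalue
            )
    return IndependentTestResult(scores, float(pcc), float(pcc_p), group_p, n_s, n_r)
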