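"""LDA classification and performance metrics.

The classifier is a linear discriminant (SVD solver, robust to feature
dimensionality far above the sample count) preceded by per-feature
z-scoring fitted on the training data only.  Performance is summarized
by accuracy, Cohen's kappa and ROC AUC (macro one-vs-rest for more than
two classes) under three validation schemes: stratified 10-fold CV,
ten random stratified 80/20 train/test splits, or a fixed held-out test
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = ["EvalResult", "fit_lda", "lda_coefficients", "cohen_kappa",
           "auc_score", "evaluate"]

SCHEMES = ("kfold10", "split2080x10", "fixed_test")


@dataclass
class EvalResult:
    """Pooled and per-fold classification metrics."""

    acc: float                       # percent, pooled confusion diagonal
    kappa: float
    auc: float
    acc_std: float                   # across folds, percent
    kappa_std: float
    auc_std: float
    per_fold: List[Tuple[float, float, float]]
    scheme: str
    confusion: np.ndarray = field(default=None, repr=False, compare=False)

    def summary(self) -> str:
        return (f"{self.scheme}: ACC {self.acc:.1f}+/-{self.acc_std:.1f} %  "
                f"kappa {self.kappa:.2f}+/-{self.kappa_std:.2f}  "
                f"AUC {self.auc:.2f}+/-{self.auc_std:.2f}")


def fit_lda(features: np.ndarray, labels: np.ndarray) -> Pipeline:
    """Standardize features and fit an SVD-solver LDA.

    Exposes per-class coefficient vectors via :func:`lda_coefficients`
    for relevance analysis.
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to fit LDA")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    model = Pipeline([
        ("scale", StandardScaler()),
        ("lda", LinearDiscriminantAnalysis(solver="svd")),
    ])
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*collinear.*")
        model.fit(features, labels)
    return model


def lda_coefficients(model: Pipeline) -> np.ndarray:
    """Discriminant coefficient matrix ``(n_discriminants, n_features)``."""
    return np.atleast_2d(model.named_steps["lda"].coef_)


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a square confusion matrix.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_e`` the marginal-product
    expected agreement; returns 0 (with a warning) when ``p_e = 1``.
    """
    cm = np.asarray(confusion, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / n
    marg = (cm.sum(axis=1) / n) @ (cm.sum(axis=0) / n)
    if np.isclose(marg, 1.0):
        warnings.warn("degenerate marginals (p_e = 1); kappa set to 0",
                      RuntimeWarning)
        return 0.0
    return float((p_o - marg) / (1.0 - marg))


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC AUC; macro one-vs-rest beyond two classes.

    For the binary case this equals the normalized Mann-Whitney U
    statistic of the positive-class scores.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("AUC undefined for a single class")
    if classes.size == 2:
        s = scores[:, 1] if scores.ndim == 2 else scores
        return float(roc_auc_score(labels, s))
    return float(roc_auc_score(labels, scores, multi_class="ovr",
                               average="macro", labels=classes))


def _fold_metrics(model: Pipeline, X_te, y_te, classes) -> Tuple[float, float, float, np.ndarray, np.ndarray]:
    pred = model.predict(X_te)
    cm = confusion_matrix(y_te, pred, labels=classes)
    acc = 100.0 * np.trace(cm) / cm.sum()
    kap = cohen_kappa(cm)
    prob = model.predict_proba(X_te)
    try:
        auc = auc_score(prob if classes.size > 2 else prob[:, 1], y_te)
    except ValueError:          # a fold may miss a class in tiny sets
        auc = np.nan
    return acc, kap, auc, pred, prob


def evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    scheme: str = "kfold10",
    seed: int = 0,
    n_folds: int = 10,
    test_features: Optional[np.ndarray] = None,
    test_labels: Optional[np.ndarray] = None,
) -> EvalResult:
    """Run the requested validation scheme and pool the metrics.

    ``kfold10``: stratified k-fold (k = ``n_folds``) with shuffling.
    ``split2080x10``: ``n_folds`` random stratified splits, 80 % train /
    20 % test.  ``fixed_test``: train on ``features`` and report on the
    provided ``test_features`` / ``test_labels``.

    The headline accuracy is 100 x the diagonal mass of the confusion
    matrix pooled over all folds; kappa is computed on the pooled
    confusion and AUC on the pooled out-of-fold scores.
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)

    if scheme == "fixed_test":
        if test_features is None or test_labels is None:
            raise ValueError("fixed_test scheme needs test_features/test_labels")
        splits = [(np.arange(len(labels)), None)]
    elif scheme == "kfold10":
        counts = np.bincount(np.searchsorted(classes, labels))
        if counts.min() < n_folds:
            raise ValueError(f"stratified {n_folds}-fold needs >= {n_folds} "
                             "samples per class")
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(cv.split(features, labels))
    elif scheme == "split2080x10":
        cv = StratifiedShuffleSplit(n_splits=n_folds, test_size=0.2,
                                    random_state=seed)
        splits = list(cv.split(features, labels))
    else:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")

    per_fold: List[Tuple[float, float, float]] = []
    pooled_cm = np.zeros((classes.size, classes.size))
    pooled_scores: List[np.ndarray] = []
    pooled_labels: List[np.ndarray] = []
    for train_idx, test_idx in splits:
        if scheme == "fixed_test":
            X_tr, y_tr = features, labels
            X_te = np.asarray(test_features, float)
            y_te = np.asarray(test_labels)
        else:
            X_tr, y_tr = features[train_idx], labels[train_idx]
            X_te, y_te = features[test_idx], labels[test_idx]
        model = fit_lda(X_tr, y_tr)
        acc, kap, auc, pred, prob = _fold_metrics(model, X_te, y_te, classes)
        per_fold.append((acc, kap, auc))
        pooled_cm += confusion_matrix(y_te, pred, labels=classes)
        pooled_scores.append(prob)
        pooled_labels.append(y_te)

    arr = np.asarray(per_fold, float)
    prob_all = np.vstack(pooled_scores)
    y_all = np.concatenate(pooled_labels)
    pooled_auc = auc_score(prob_all if classes.size > 2 else prob_all[:, 1],
                           y_all)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*empty slice.*")
        fold_std = np.nanstd(arr, axis=0)
    return EvalResult(
        acc=float(100.0 * np.trace(pooled_cm) / pooled_cm.sum()),
        kappa=cohen_kappa(pooled_cm),
        auc=float(pooled_auc),
        acc_std=float(fold_std[0]),
        kappa_std=float(fold_std[1]),
        auc_std=float(fold_std[2]),
        per_fold=[tuple(map(float, row)) for row in per_fold],
        scheme=scheme,
        confusion=pooled_cm,
    )
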