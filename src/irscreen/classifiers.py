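"""Discriminant classifiers: Mahalanobis LDA/QDA and RBF-kernel SVM.

LDA and QDA are used in their non-Bayesian form: the classification score of
sample x for class k is the squared Mahalanobis distance

    L_k(x) = (x - m_k)^T C_pooled^{-1} (x - m_k)        (LDA)
    Q_k(x) = (x - m_k)^T C_k^{-1}      (x - m_k)        (QDA)

with no log-determinant or prior terms; the predicted class minimizes the
score.  LDA pools the class covariances (equal-dispersion assumption), QDA
keeps each class's own covariance.

The SVM is the usual soft-margin machine with the radial basis function
kernel k(x, z) = exp(-gamma * ||x - z||^2) and decision rule
f(z) = sign(sum_i alpha_i y_i k(x_i, z) + b) over the support vectors.
The box constraint C is tuned on a validation set; gamma defaults to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .reduction import ClassStatistics, fit_class_statistics

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


# ---------------------------------------------------------------------------
# LDA / QDA
# ---------------------------------------------------------------------------


@dataclass
class DiscriminantModel:
    """Fitted Mahalanobis discriminant (lda uses the pooled covariance only)."""

    stats: ClassStatistics
    mode: str  # 'lda' | 'qda'

    def __post_init__(self) -> None:
        if self.mode not in ("lda", "qda"):
            raise ValueError(f"mode must be 'lda' or 'qda', got {self.mode!r}")

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "classes": self.stats.classes.tolist(),
            "means": self.stats.means.tolist(),
            "pooled_cov": self.stats.pooled_cov.tolist(),
            "class_covs": self.stats.class_covs.tolist(),
        }


def fit_discriminant(X_train: np.ndarray, y_train: np.ndarray, mode: str) -> DiscriminantModel:
    """Fit class means plus pooled (lda) or per-class (qda) covariances.

    Requires at least two samples per class; covariances are ridged to
    positive definiteness when needed.
    """
    return DiscriminantModel(stats=fit_class_statistics(X_train, y_train), mode=mode)


def _scores(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """(n, n_classes) matrix of squared Mahalanobis scores."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    stats = model.stats
    out = np.empty((X.shape[0], stats.classes.size))
    for k in range(stats.classes.size):
        C = stats.pooled_cov if model.mode == "lda" else stats.class_covs[k]
        L = np.linalg.cholesky(C)
        w = np.linalg.solve(L, (X - stats.means[k]).T)
        out[:, k] = np.sum(w * w, axis=0)
    return out


def discriminant_score(model: DiscriminantModel, x: np.ndarray, k) -> float:
    """Score of sample ``x`` for class ``k`` (smaller = closer)."""
    col = int(np.searchsorted(model.stats.classes, k))
    if col >= model.stats.classes.size or model.stats.classes[col] != k:
        raise ValueError(f"unknown class {k!r}")
    return float(_scores(model, np.atleast_2d(x))[0, col])


def classify_discriminant(model: DiscriminantModel, X: np.ndarray):
    """Minimal-score classification with a margin score for ROC.

    Returns ``(labels, margins, tie_flags)``.  The margin is
    score(negative class) - score(positive class): larger means more
    positive-like.  Exact ties go to the positive class and are flagged —
    in a screening context a borderline case should not be called healthy.
    """
    scores = _scores(model, X)
    classes = model.stats.classes
    pos_col = int(np.argmax(classes))  # positive class = 1, negative = 0
    neg_col = int(np.argmin(classes))
    margins = scores[:, neg_col] - scores[:, pos_col]
    labels = np.where(margins >= 0, classes[pos_col], classes[neg_col])
    ties = margins == 0
    if ties.any():
        logger.info("classify_discriminant: %d tie(s) resolved to positive class",
                    int(ties.sum()))
    return labels, margins, ties


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------


@dataclass
class SvmModel:
    """Dual solution of the soft-margin RBF SVM."""

    support_vectors: np.ndarray  # (n_sv, p)
    alphas: np.ndarray  # multipliers alpha_i >= 0
    sv_labels: np.ndarray  # y_i in {-1, +1}
    bias: float
    gamma: float
    C: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_sv(self) -> int:
        return self.support_vectors.shape[0]

    def to_json_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "C": self.C,
            "bias": self.bias,
            "alphas": self.alphas.tolist(),
            "sv_labels": self.sv_labels.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "provenance": self.provenance,
        }


def rbf_kernel(x: np.ndarray, z: np.ndarray, gamma: float) -> float:
    """k(x, z) = exp(-gamma * ||x - z||^2), in (0, 1] for gamma > 0."""
    d = np.asarray(x, dtype=float) - np.asarray(z, dtype=float)
    return float(np.exp(-gamma * np.dot(d, d)))


def _to_pm1(y: np.ndarray) -> np.ndarray:
    """Map {0,1} (or already ±1) labels to {-1,+1}."""
    y = np.asarray(y)
    vals = set(np.unique(y).tolist())
    if vals <= {-1, 1}:
        return y.astype(int)
    if vals <= {0, 1}:
        return np.where(y == 1, 1, -1)
    raise ValueError(f"labels must be binary 0/1 or ±1, got {sorted(vals)}")


def _fit_single_svm(X: np.ndarray, y_pm: np.ndarray, gamma: float, C: float) -> SvmModel:
    clf = SVC(C=C, kernel="rbf", gamma=gamma, tol=1e-6)
    clf.fit(X, y_pm)
    # sklearn's dual_coef_ holds alpha_i * y_i for the support vectors
    dual = clf.dual_coef_.ravel()
    sv = clf.support_vectors_
    y_sv = np.sign(dual).astype(int)
    alphas = np.abs(dual)
    return SvmModel(
        support_vectors=sv,
        alphas=alphas,
        sv_labels=y_sv,
        bias=float(clf.intercept_[0]),
        gamma=gamma,
        C=C,
    )


def fit_svm(
    X_train: np.ndarray,
    y_train: np.ndarray,
    gamma: float = 1.0,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    X_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
) -> SvmModel:
    """Fit the soft-margin RBF SVM, tuning C on the validation set.

    For each C in ``C_grid`` (ascending) the dual problem is solved and
    validation accuracy measured; the smallest C attaining the maximum
    accuracy is kept.  Without a validation set the first C in the grid is
    used.  Labels may be 0/1 or ±1.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_pm = _to_pm1(y_train)
    if X_val is None:
        model = _fit_single_svm(X_train, y_pm, gamma, float(sorted(C_grid)[0]))
        model.provenance.update({"C_grid": list(C_grid), "tuned": False})
        return model
    y_val_pm = _to_pm1(y_val)
    best = None  # (accuracy, -C) maximized => ties -> smaller C
    for C in sorted(C_grid):
        model = _fit_single_svm(X_train, y_pm, gamma, float(C))
        acc = float(np.mean(svm_classify(model, X_val)[0] == y_val_pm))
        if best is None or acc > best[0]:
            best = (acc, model)
    acc, model = best
    model.provenance.update(
        {"C_grid": [float(c) for c in C_grid], "tuned": True, "val_accuracy": acc}
    )
    return model


def svm_decision(model: SvmModel, Z: np.ndarray) -> np.ndarray:
    """Decision values sum_i alpha_i y_i k(x_i, z) + b for each row z."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    K = np.exp(-model.gamma * cdist(Z, model.support_vectors, "sqeuclidean"))
    return K @ (model.alphas * model.sv_labels) + model.bias


def svm_classify(model: SvmModel, Z: np.ndarray):
    """Sign rule on the decision value; zeros go to the positive class.

    Returns ``(labels in {-1,+1}, tie_flags)``.
    """
    dec = svm_decision(model, Z)
    labels = np.where(dec >= 0, 1, -1)
    ties = dec == 0
    if ties.any():
        logger.info("svm_classify: %d zero decision value(s) resolved to +1",
                    int(ties.sum()))
    return labels, ties
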