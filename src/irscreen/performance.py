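"""Confusion matrix, diagnostic figures of merit, and ROC/AUC.

Eight figures of merit summarize a binary screening test, all expressed as
percentages of the confusion counts (TP, FN, FP, TN):

    AC   = (TP+TN)/(TP+FP+TN+FN) * 100         accuracy
    SENS = TP/(TP+FN) * 100                    sensitivity
    SPEC = TN/(TN+FP) * 100                    specificity
    YOU  = SENS - (100 - SPEC)                 Youden's index
    PPV  = TP/(TP+FP) * 100                    positive predictive value
    NPV  = TN/(TN+FN) * 100                    negative predictive value
    F    = 2*SENS*SPEC/(SENS+SPEC)
    G    = sqrt(SENS*SPEC)

.. warning::
   The F-score here is the harmonic mean of sensitivity and SPECIFICITY —
   a convention common in chemometric screening papers — not the usual
   precision/recall F1.  The G-score is likewise the geometric mean of
   SENS and SPEC.

Metrics are kept at full precision internally; display rounding (half away
from zero, one decimal) is applied only when formatting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts (positive = disease class)."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FN", "FP", "TN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN

    @property
    def positives(self) -> int:
        return self.TP + self.FN

    @property
    def negatives(self) -> int:
        return self.TN + self.FP


@dataclass(frozen=True)
class PerformanceReport:
    """The eight figures of merit (percent) plus AUC (fraction).

    ``PPV``/``NPV`` are ``None`` when their denominator is zero (no positive
    or no negative calls) — undefined, not 0.
    """

    AC: float
    SENS: float
    SPEC: float
    YOU: float
    PPV: Optional[float]
    NPV: Optional[float]
    F_score: float
    G_score: float
    AUC: Optional[float] = None

    def rounded(self) -> dict:
        """Display form: one decimal, half away from zero; AUC to 3 decimals."""
        out = {}
        for name in ("AC", "SENS", "SPEC", "YOU", "PPV", "NPV", "F_score", "G_score"):
            v = getattr(self, name)
            out[name] = None if v is None else round_half_away(v, 1)
        out["AUC"] = None if self.AUC is None else round_half_away(self.AUC, 3)
        return out


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (printed-table convention)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def confusion(y_true: np.ndarray, y_pred: np.ndarray, positive=1) -> ConfusionMatrix:
    """Count TP/FN/FP/TN with ``positive`` as the disease label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionMatrix(
        TP=int(np.sum(t & p)),
        FN=int(np.sum(t & ~p)),
        FP=int(np.sum(~t & p)),
        TN=int(np.sum(~t & ~p)),
    )


def figures_of_merit(cm: ConfusionMatrix, auc: Optional[float] = None) -> PerformanceReport:
    """The eight figures of merit from a confusion matrix.

    Requires at least one true positive+false negative and one true
    negative+false positive (SENS and SPEC must be defined).
    """
    if cm.positives == 0 or cm.negatives == 0:
        raise ValueError("SENS/SPEC undefined: need >=1 positive and >=1 negative")
    sens = 100.0 * cm.TP / cm.positives
    spec = 100.0 * cm.TN / cm.negatives
    ac = 100.0 * (cm.TP + cm.TN) / cm.total
    you = sens - (100.0 - spec)
    ppv = 100.0 * cm.TP / (cm.TP + cm.FP) if (cm.TP + cm.FP) > 0 else None
    npv = 100.0 * cm.TN / (cm.TN + cm.FN) if (cm.TN + cm.FN) > 0 else None
    f = 2.0 * sens * spec / (sens + spec) if (sens + spec) > 0 else 0.0
    g = float(np.sqrt(sens * spec))
    return PerformanceReport(AC=ac, SENS=sens, SPEC=spec, YOU=you,
                             PPV=ppv, NPV=npv, F_score=f, G_score=g, AUC=auc)


def roc(scores: np.ndarray, y_true: np.ndarray, positive=1):
    """ROC curve and AUC for continuous scores (larger = more positive-like).

    The curve is the threshold sweep over the unique scores; the AUC equals
    the Mann-Whitney statistic (probability a random positive outscores a
    random negative, ties counted 1/2).
    """
    y = np.asarray(y_true) == positive
    scores = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC requires at least one positive and one negative")
    fpr, tpr, thresholds = roc_curve(y.astype(int), scores)
    auc = float(roc_auc_score(y.astype(int), scores))
    return fpr, tpr, thresholds, auc
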