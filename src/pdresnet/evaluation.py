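"""Confusion matrix, classification metrics and ROC/AUC.

The four confusion cells follow the clinical naming of the task: T_HC
and T_PD count correctly classified controls and patients, F_HC counts
patients predicted as controls, F_PD controls predicted as patients.
Accuracy, precision, recall and specificity are reported on the
percentage scale; F1 is the harmonic mean of precision and recall (also
percentage-scale). A metric whose denominator is zero is reported as
undefined (``None``), never silently as 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "f1_from_precision_recall",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts for a binary task (positive class = PD by convention)."""
    t_hc: int   # true negatives: HC classified HC
    t_pd: int   # true positives: PD classified PD
    f_hc: int   # PD predicted HC (missed patients)
    f_pd: int   # HC predicted PD (false alarms)

    def __post_init__(self) -> None:
        for name in ("t_hc", "t_pd", "f_hc", "f_pd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.t_hc + self.t_pd + self.f_hc + self.f_pd

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.t_hc, self.f_pd], [self.f_hc, self.t_pd]],
            index=pd.Index(["HC", "PD"], name="true"),
            columns=pd.Index(["HC", "PD"], name="predicted"))


@dataclass(frozen=True)
class MetricsReport:
    """Percentage-scale metrics; ``None`` marks an undefined metric."""
    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    auc: float | None = None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        out = {}
        for name in ("accuracy", "precision", "recall", "specificity", "f1"):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, ndigits)
        out["auc"] = None if self.auc is None else round(self.auc, 3)
        return out

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name)
                for name in ("accuracy", "precision", "recall",
                             "specificity", "f1", "auc")}


def confusion(predicted, true) -> ConfusionMatrix:
    """Tally the four cells; label 1 is the positive (PD) class."""
    pred = np.asarray(predicted, dtype=int)
    y = np.asarray(true, dtype=int)
    if pred.shape != y.shape:
        raise ValueError(
            f"predicted and true label sequences differ in length: "
            f"{pred.shape} vs {y.shape}")
    return ConfusionMatrix(
        t_hc=int(np.sum((pred == 0) & (y == 0))),
        t_pd=int(np.sum((pred == 1) & (y == 1))),
        f_hc=int(np.sum((pred == 0) & (y == 1))),
        f_pd=int(np.sum((pred == 1) & (y == 0))),
    )


def _ratio_percent(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def f1_from_precision_recall(precision: float | None,
                             recall: float | None) -> float | None:
    """Harmonic mean of percentage-scale precision and recall."""
    if precision is None or recall is None or precision + recall == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall, specificity and F1 from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("metrics of an empty confusion matrix are undefined")
    pre = _ratio_percent(cm.t_pd, cm.t_pd + cm.f_pd)
    rec = _ratio_percent(cm.t_pd, cm.t_pd + cm.f_hc)
    return MetricsReport(
        accuracy=_ratio_percent(cm.t_hc + cm.t_pd, cm.total),
        precision=pre,
        recall=rec,
        specificity=_ratio_percent(cm.t_hc, cm.t_hc + cm.f_pd),
        f1=f1_from_precision_recall(pre, rec),
    )


def roc_auc(scores, true) -> tuple[pd.DataFrame, float]:
    """ROC curve (threshold sweep over all distinct scores) and its AUC.

    The AUC equals the probability that a random positive outscores a
    random negative, ties counting one half — the trapezoidal area under
    the curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(true, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return curve, float(_trapezoid_auc(fpr, tpr))
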