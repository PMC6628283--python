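"""Diagnostic-classifier metric suite.

Binary confusion-matrix metrics (accuracy, sensitivity, specificity,
precision, recall, F-measure), Cohen's kappa, the rank-based (Mann-Whitney)
AUC computed from continuous classifier scores, and the conventional verbal
bands for AUC values.  Degenerate 0/0 ratios are reported as 0 with a
:class:`MetricWarning` rather than NaN so result tables stay comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "MetricWarning",
    "confusion_matrix",
    "classification_metrics",
    "cohen_kappa",
    "rank_auc",
    "auc_category",
    "compute_metrics",
]


class MetricWarning(UserWarning):
    """Emitted when a metric's denominator is zero and 0 is substituted."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 cross-tabulation of true vs predicted class for one positive class."""

    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricSet:
    """The full metric suite for one evaluated model (or fold average)."""

    accuracy: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    precision: float = np.nan
    recall: float = np.nan
    f_measure: float = np.nan
    kappa: float = np.nan
    auc: float = np.nan
    auc_category: str = ""

    def value(self, name: str) -> float:
        return getattr(self, name)

    @staticmethod
    def mean(sets: list["MetricSet"]) -> "MetricSet":
        """Field-wise mean (fold averaging); the AUC band is re-derived."""
        if not sets:
            raise ValueError("cannot average an empty list of metric sets")
        out = MetricSet()
        for f in fields(MetricSet):
            if f.name == "auc_category":
                continue
            setattr(out, f.name, float(np.mean([getattr(s, f.name) for s in sets])))
        out.auc_category = auc_category(out.auc) if np.isfinite(out.auc) else ""
        return out


def _as_binary(truth, predicted, positive_class):
    t = np.asarray(truth, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if t.shape != p.shape:
        raise ValueError("truth and predicted must have equal length")
    classes = np.unique(np.concatenate([t, p]))
    if classes.size > 2:
        raise ValueError(
            f"binary metrics require at most two classes, found {classes.size}"
        )
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class} not present")
    return t, p


def confusion_matrix(truth, predicted, positive_class) -> ConfusionMatrix:
    """Standard 2x2 cross-tabulation for a binary task."""
    t, p = _as_binary(truth, predicted, positive_class)
    pos_t = t == positive_class
    pos_p = p == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        positive_class=float(positive_class),
    )


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 denominator, reporting 0", MetricWarning,
                      stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, sensitivity, specificity, precision, recall and F-measure.

    ACC = (TP+TN)/(TP+FP+FN+TN); sensitivity = recall = TP/(TP+FN);
    specificity = TN/(TN+FP); precision = TP/(TP+FP);
    F = 2 * precision * recall / (precision + recall).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / cm.total
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    prec = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    rec = sens
    f = _ratio(2 * prec * rec, prec + rec, "f-measure")
    return MetricSet(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        recall=rec,
        f_measure=f,
    )


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed accuracy and p_e the marginal-product chance
    agreement.  When p_e = 1 (both raters constant), kappa is 1 for perfect
    agreement and otherwise 0 with a warning.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = (cm.tp + cm.tn) / n
    p_pos = ((cm.tp + cm.fn) / n) * ((cm.tp + cm.fp) / n)
    p_neg = ((cm.fp + cm.tn) / n) * ((cm.fn + cm.tn) / n)
    p_e = p_pos + p_neg
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        warnings.warn("kappa: 0/0 denominator, reporting 0", MetricWarning,
                      stacklevel=2)
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def rank_auc(truth, scores, positive_class) -> float:
    """Mann-Whitney AUC: probability a random positive outscores a random negative.

    AUC = [#(pos > neg) + 0.5 * #(ties)] / (n_pos * n_neg), computed from
    midranks; scores must be oriented so that larger means more positive.
    """
    t = np.asarray(truth, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if t.shape != s.shape:
        raise ValueError("truth and scores must have equal length")
    pos = t == positive_class
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)  # midranks handle ties with 0.5 credit
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


#: lower-inclusive AUC bands; the verbal labels are the conventional ones
_AUC_BANDS = (
    (0.9, "excellent classification"),
    (0.8, "good classification"),
    (0.7, "fair classification"),
    (0.6, "poor classification"),
    (0.5, "failure"),
)


def auc_category(auc: float) -> str:
    """Verbal band for an AUC value (lower-inclusive at each boundary)."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC {auc} outside [0, 1]")
    for lo, label in _AUC_BANDS:
        if auc >= lo:
            return label
    return "worse than chance"


def compute_metrics(truth, predicted, scores, positive_class) -> MetricSet:
    """Assemble the full metric suite for one prediction run.

    ``scores`` are the continuous classifier outputs used for the rank AUC;
    pass ``None`` to skip the AUC (it stays NaN with an empty band label).
    """
    cm = confusion_matrix(truth, predicted, positive_class)
    ms = classification_metrics(cm)
    ms.kappa = cohen_kappa(cm)
    if scores is not None:
        ms.auc = rank_auc(truth, scores, positive_class)
        ms.auc_category = auc_category(ms.auc)
    return ms
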