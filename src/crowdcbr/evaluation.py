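"""Imbalance-aware evaluation: confusion matrix, per-class rates,
micro/macro aggregation, predictive values and ROC/AUC.

Plain accuracy is uninformative under heavy class imbalance (predicting
the majority everywhere already scores ratio/(ratio+1)), so reports
here always carry per-class TP/FP rates, precision and recall, their
prevalence-weighted ("overall") and unweighted macro ("overall norm")
aggregates, predictive values, and the ROC operating point with its
trapezoid-rule AUC.  The minority (abnormal/"serious") class is the
ROC-positive class throughout.

Predictive values are reported in two labelled variants, because both
conventions occur in practice: the textbook definition
PPV = TP/(TP+FP), NPV = TN/(TN+FN), and the per-class-recall reading
(PPV = minority TP rate, NPV = majority TP rate).  Undefined metrics
(zero denominators) are emitted as NaN sentinels and logged, never as
silent zeros.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

from .errors import DomainError
from .io_survey import ABNORMAL, NORMAL

logger = logging.getLogger(__name__)

#: Sentinel for a metric whose denominator is zero.
UNDEFINED = math.nan


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.6055 -> 0.606 at 3 digits)."""
    import decimal

    x = float(x)
    if math.isnan(x):
        return x
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with the minority (abnormal) class as positive."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise DomainError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def swapped(self) -> "ConfusionMatrix":
        """The same predictions with the other class as positive."""
        return ConfusionMatrix(tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp)


def confusion(true_labels, predicted_labels, positive_class: str = ABNORMAL) -> ConfusionMatrix:
    """Count TP/FN/FP/TN for a pair of label vectors."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise DomainError("label vectors must have equal length")
    known = {NORMAL, ABNORMAL}
    tp = fn = fp = tn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t not in known or p not in known:
            raise DomainError(f"unknown label in pair ({t!r}, {p!r})")
        if t == positive_class:
            tp += p == positive_class
            fn += p != positive_class
        else:
            fp += p == positive_class
            tn += p != positive_class
    return ConfusionMatrix(tp, fn, fp, tn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("metric %s undefined (zero denominator)", name)
        return UNDEFINED
    return num / den


def basic_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, TP rate, FP rate, precision and recall from one matrix."""
    return {
        "accuracy": _ratio(cm.tp + cm.tn, cm.total, "accuracy"),
        "tp_rate": _ratio(cm.tp, cm.tp + cm.fn, "tp_rate"),
        "fp_rate": _ratio(cm.fp, cm.fp + cm.tn, "fp_rate"),
        "precision": _ratio(cm.tp, cm.tp + cm.fp, "precision"),
        "recall": _ratio(cm.tp, cm.tp + cm.fn, "recall"),
    }


def macro_average(values, ndigits: int | None = None) -> float:
    """Unweighted mean over classes (the "overall (norm)" convention).

    Pass ``ndigits`` to round half-up for reporting.
    """
    values = list(values)
    if not values:
        raise DomainError("macro average of no values")
    mean = sum(values) / len(values)
    return round_half_up(mean, ndigits) if ndigits is not None else mean


def weighted_average(values, counts) -> float:
    """Prevalence-weighted mean over classes (the "overall" convention)."""
    values = list(values)
    counts = list(counts)
    if len(values) != len(counts) or not values:
        raise DomainError("values and counts must be equal-length and non-empty")
    if any(c < 0 for c in counts):
        raise DomainError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise DomainError("zero total count")
    return sum(v * c for v, c in zip(values, counts)) / total


def ppv_npv(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """Both conventions of predictive values, labelled.

    ``textbook``: PPV = TP/(TP+FP), NPV = TN/(TN+FN).
    ``per_class_recall``: PPV = minority TP rate, NPV = majority TP rate.
    """
    return {
        "textbook": {
            "ppv": _ratio(cm.tp, cm.tp + cm.fp, "ppv"),
            "npv": _ratio(cm.tn, cm.tn + cm.fn, "npv"),
        },
        "per_class_recall": {
            "ppv": _ratio(cm.tp, cm.tp + cm.fn, "ppv(recall)"),
            "npv": _ratio(cm.tn, cm.tn + cm.fp, "npv(recall)"),
        },
    }


@dataclass
class ROCCurve:
    """Ordered (FP rate, TP rate) points from (0,0) to (1,1)."""

    points: list[tuple[float, float]]

    def __post_init__(self):
        if len(self.points) < 2:
            raise DomainError("an ROC curve needs at least 2 points")
        if self.points[0] != (0.0, 0.0) or self.points[-1] != (1.0, 1.0):
            raise DomainError("ROC curve must run from (0,0) to (1,1)")
        fprs = [p[0] for p in self.points]
        if any(b < a for a, b in zip(fprs, fprs[1:])):
            raise DomainError("ROC FP rates must be non-decreasing")


def roc_from_point(cm: ConfusionMatrix) -> ROCCurve:
    """Single-operating-point curve of a discrete classifier:
    (0,0) -> (FP rate, TP rate) -> (1,1)."""
    m = basic_metrics(cm)
    if math.isnan(m["tp_rate"]) or math.isnan(m["fp_rate"]):
        raise DomainError("TP or FP rate undefined; cannot build an ROC point")
    return ROCCurve([(0.0, 0.0), (m["fp_rate"], m["tp_rate"]), (1.0, 1.0)])


def roc_from_scores(true_labels, scores, positive_class: str = ABNORMAL) -> ROCCurve:
    """Threshold sweep over a continuous score, descending, ties grouped.

    Constant scores yield the degenerate two-point diagonal.
    """
    true_labels = list(true_labels)
    scores = [float(s) for s in scores]
    if len(true_labels) != len(scores):
        raise DomainError("labels and scores must have equal length")
    if any(not math.isfinite(s) for s in scores):
        raise DomainError("scores must be finite")
    n_pos = sum(t == positive_class for t in true_labels)
    n_neg = len(true_labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DomainError("both classes must be present to sweep an ROC curve")
    if len(set(scores)) == 1:
        return ROCCurve([(0.0, 0.0), (1.0, 1.0)])
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            tp += true_labels[order[j]] == positive_class
            fp += true_labels[order[j]] != positive_class
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return ROCCurve(points)


def auc(curve: ROCCurve) -> float:
    """Area under the curve by the trapezoid rule:
    sum over segments of TPrate_i * dFPR + dTPR * dFPR / 2."""
    area = 0.0
    for (x0, y0), (x1, y1) in zip(curve.points, curve.points[1:]):
        area += y0 * (x1 - x0) + 0.5 * (y1 - y0) * (x1 - x0)
    return area


@dataclass
class MetricsReport:
    """Everything an imbalance-aware comparison table needs."""

    confusion_matrix: ConfusionMatrix
    per_class: dict[str, dict[str, float]]
    overall_accuracy: float  # percent
    overall: dict[str, float]
    overall_norm: dict[str, float]
    predictive_values: dict[str, dict[str, float]]
    auc_single_point: float
    class_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        cm = self.confusion_matrix
        return {
            "confusion_matrix": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
            "class_counts": self.class_counts,
            "overall_accuracy": self.overall_accuracy,
            "per_class": self.per_class,
            "overall": self.overall,
            "overall_norm": self.overall_norm,
            "predictive_values": self.predictive_values,
            "auc_single_point": self.auc_single_point,
        }

    def to_json(self, path) -> None:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, float) and math.isnan(obj):
                return None  # JSON has no NaN; undefined metrics become null
            return obj

        with open(path, "w") as handle:
            json.dump(clean(self.to_dict()), handle, indent=1)


_RATE_KEYS = ("tp_rate", "fp_rate", "precision", "recall")


def metrics_report(true_labels, predicted_labels, positive_class: str = ABNORMAL) -> MetricsReport:
    """Full evaluation of a batch of discrete predictions.

    Per-class rows treat each class in turn as positive (as comparison
    tables conventionally print them); "overall" rows are prevalence
    weighted, "overall (norm)" rows are plain macro means.  Rates are
    rounded half-up to 3 decimals, overall accuracy to 4 decimals of
    percent.
    """
    cm = confusion(true_labels, predicted_labels, positive_class)
    negative_class = NORMAL if positive_class == ABNORMAL else ABNORMAL
    per_class_cm = {negative_class: cm.swapped(), positive_class: cm}
    per_class = {
        cls: {k: round_half_up(v, 3) for k, v in basic_metrics(m).items() if k != "accuracy"}
        for cls, m in per_class_cm.items()
    }
    counts = {negative_class: cm.fp + cm.tn, positive_class: cm.tp + cm.fn}
    overall = {
        k: round_half_up(
            weighted_average(
                [basic_metrics(per_class_cm[c])[k] for c in per_class_cm],
                [counts[c] for c in per_class_cm],
            ), 3)
        for k in _RATE_KEYS
    }
    overall_norm = {
        k: macro_average([basic_metrics(per_class_cm[c])[k] for c in per_class_cm], ndigits=3)
        for k in _RATE_KEYS
    }
    return MetricsReport(
        confusion_matrix=cm,
        per_class=per_class,
        overall_accuracy=round_half_up(100.0 * basic_metrics(cm)["accuracy"], 4),
        overall=overall,
        overall_norm=overall_norm,
        predictive_values=ppv_npv(cm),
        auc_single_point=auc(roc_from_point(cm)),
        class_counts=counts,
    )
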