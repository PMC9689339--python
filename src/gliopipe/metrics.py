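"""Classification and segmentation evaluation.

Confusion-matrix rates (accuracy, precision, recall/sensitivity,
specificity, F-measure), Dice similarity, and the mutual information of
two binary masks computed from their 2x2 joint pixel-label histogram in
bits.  Ratios with a zero denominator are reported as ``None`` rather than
silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion_metrics",
    "dice",
    "mask_confusion",
    "mutual_information",
    "multiclass_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvaluationReport:
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f_measure: float | None = None
    specificity: float | None = None
    sensitivity: float | None = None
    dsc: float | None = None
    mutual_information: float | None = None
    per_class: dict | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(counts: ConfusionCounts) -> EvaluationReport:
    """Classification rates from TP/FP/TN/FN counts."""
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    if precision is None or recall is None or precision + recall == 0:
        f = None
    else:
        f = 2 * precision * recall / (precision + recall)
    return EvaluationReport(
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=precision,
        recall=recall,
        f_measure=f,
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        sensitivity=recall,
    )


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask, dtype=bool)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); two empty masks score 1.0."""
    a, b = _as_bool(mask_a), _as_bool(mask_b)
    _check_shapes(a, b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def mask_confusion(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts of a predicted vs reference binary mask."""
    p, t = _as_bool(pred_mask), _as_bool(true_mask)
    _check_shapes(p, t)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def mutual_information(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Mutual information of two binary masks, in bits.

    Computed from the 2x2 joint histogram of per-pixel labels; equals the
    entropy of a mask when compared with itself.
    """
    a, b = _as_bool(mask_a), _as_bool(mask_b)
    _check_shapes(a, b)
    n = a.size
    joint = np.array(
        [
            [np.sum(~a & ~b), np.sum(~a & b)],
            [np.sum(a & ~b), np.sum(a & b)],
        ],
        dtype=np.float64,
    ) / n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz]))
    return float(max(mi, 0.0))


def multiclass_report(
    pred_labels: np.ndarray, true_labels: np.ndarray, classes: list
) -> EvaluationReport:
    """One-vs-rest evaluation per class plus unweighted macro averages.

    The report's headline rates are macro averages over the per-class
    one-vs-rest confusion matrices; macro accuracy is the mean of the
    per-class accuracies.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("prediction and truth must be equal-length and nonempty")
    unknown = set(np.unique(pred)) | set(np.unique(true))
    unknown -= set(classes)
    if unknown:
        raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    per_class = {}
    for cls in classes:
        counts = mask_confusion(pred == cls, true == cls)
        per_class[cls] = confusion_metrics(counts)
    def _macro(attr):
        vals = [getattr(r, attr) for r in per_class.values()]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None
    return EvaluationReport(
        accuracy=_macro("accuracy"),
        precision=_macro("precision"),
        recall=_macro("recall"),
        f_measure=_macro("f_measure"),
        specificity=_macro("specificity"),
        sensitivity=_macro("sensitivity"),
        per_class={cls: r.to_dict() for cls, r in per_class.items()},
    )
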