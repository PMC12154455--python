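"""Detection/segmentation evaluation: P, R, AP/mAP, confusion accuracies.

Precision and recall are the usual ratios over matched detections:

    P = TP / (TP + FP)        R = TP / (TP + FN)

Detections are matched to ground truth greedily per class in descending
confidence at a fixed mask-IoU threshold (default 0.5); each ground
truth can absorb at most one detection.  AP is the area under the
precision-recall curve of the ranked detections, computed with 101-point
interpolation (the precision envelope sampled at recalls 0.00, 0.01, …,
1.00), and mAP is the unweighted mean of the per-class APs.

Classification results (integrity, sex) are summarised by a 2x2
confusion matrix; "average accuracy" is the macro average — the
unweighted mean of the per-class row-wise accuracies — which differs
from pooled accuracy when the classes are imbalanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_annotations import ValidationError
from .segmentation import SegmentationResult

__all__ = [
    "ConfusionMatrix2",
    "MatchedDetections",
    "mask_iou",
    "match_detections",
    "precision_recall",
    "average_precision",
    "mean_ap",
    "confusion_accuracy",
]


@dataclass(frozen=True)
class ConfusionMatrix2:
    """2x2 confusion matrix; rows = true class, columns = predicted."""

    labels: tuple[str, str]
    counts: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        flat = [c for row in self.counts for c in row]
        if any(c < 0 for c in flat):
            raise ValidationError("confusion counts must be >= 0")
        if sum(flat) == 0:
            raise ValidationError("confusion matrix is all zeros")


@dataclass
class MatchedDetections:
    """Per-class ranked (confidence, is_true_positive) pairs + truth counts."""

    pairs: dict[str, list[tuple[float, bool]]] = field(default_factory=dict)
    gt_counts: dict[str, int] = field(default_factory=dict)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def match_detections(
    predictions: Sequence[SegmentationResult],
    ground_truths: Sequence[SegmentationResult],
    iou_threshold: float = 0.5,
) -> MatchedDetections:
    """Greedy per-class matching of detections to ground truth by IoU.

    Within each class, detections are visited in descending confidence;
    each takes the still-unmatched truth of highest IoU if that IoU
    reaches the threshold (true positive), otherwise it is a false
    positive.  Truths never matched are false negatives, visible as
    ``gt_counts`` minus the per-class TP count.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValidationError(f"iou_threshold must be in (0, 1), got {iou_threshold}")
    out = MatchedDetections()
    classes = {p.class_label for p in predictions} | {g.class_label for g in ground_truths}
    for cls in sorted(classes):
        preds = sorted(
            (p for p in predictions if p.class_label == cls),
            key=lambda p: -p.confidence,
        )
        truths = [g for g in ground_truths if g.class_label == cls]
        taken = [False] * len(truths)
        pairs: list[tuple[float, bool]] = []
        for p in preds:
            best, best_iou = -1, 0.0
            for j, g in enumerate(truths):
                if taken[j]:
                    continue
                iou = mask_iou(p.mask, g.mask)
                if iou > best_iou:
                    best, best_iou = j, iou
            if best >= 0 and best_iou >= iou_threshold:
                taken[best] = True
                pairs.append((p.confidence, True))
            else:
                pairs.append((p.confidence, False))
        out.pairs[cls] = pairs
        out.gt_counts[cls] = len(truths)
    return out


def precision_recall(TP: int, FP: int, FN: int) -> tuple[float, float]:
    """Exact P and R; a zero denominator yields NaN with a warning."""
    if min(TP, FP, FN) < 0:
        raise ValidationError("TP, FP, FN must be non-negative")
    if TP + FP == 0:
        warnings.warn("precision undefined (TP + FP == 0); returning NaN", stacklevel=2)
        p = float("nan")
    else:
        p = TP / (TP + FP)
    if TP + FN == 0:
        warnings.warn("recall undefined (TP + FN == 0); returning NaN", stacklevel=2)
        r = float("nan")
    else:
        r = TP / (TP + FN)
    return p, r


def average_precision(
    matched_pairs: Sequence[tuple[float, bool]], gt_count: int
) -> float:
    """101-point interpolated AP from ranked (confidence, is_TP) pairs.

    Precision is made monotone non-increasing (the envelope) and sampled
    at recalls 0.00 … 1.00 in steps of 0.01; AP is the mean of the 101
    samples.  Recall levels never reached contribute zero.
    """
    if gt_count < 1:
        raise ValidationError("gt_count must be >= 1 for AP")
    if len(matched_pairs) == 0:
        return 0.0
    order = np.argsort([-c for c, _ in matched_pairs], kind="stable")
    tp = np.array([bool(matched_pairs[i][1]) for i in order], float)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / gt_count
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope: best precision at this recall or beyond
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    samples = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, samples, side="left")
    interp = np.where(idx < len(envelope), envelope[np.minimum(idx, len(envelope) - 1)], 0.0)
    return float(interp.mean())


def mean_ap(per_class_APs: Mapping[str, float] | Sequence[float]) -> float:
    """Arithmetic mean of per-class APs."""
    values = (
        list(per_class_APs.values())
        if isinstance(per_class_APs, Mapping)
        else list(per_class_APs)
    )
    if len(values) == 0:
        raise ValidationError("mean_ap needs at least one class AP")
    return float(np.mean(values))


def confusion_accuracy(
    cm: ConfusionMatrix2,
) -> tuple[dict[str, float], float]:
    """Per-class accuracies (diagonal / row sum) and their macro average.

    Classes with an empty row are excluded with a warning.  The macro
    average is the unweighted mean over the included classes, which is
    the convention that matches per-class test reporting (it equals
    pooled accuracy only when row sums are equal).
    """
    per_class: dict[str, float] = {}
    for i, label in enumerate(cm.labels):
        row = cm.counts[i]
        total = sum(row)
        if total == 0:
            warnings.warn(f"class '{label}' has no samples; excluded", stacklevel=2)
            continue
        per_class[label] = row[i] / total
    if not per_class:
        raise ValidationError("no class has samples")
    macro = float(np.mean(list(per_class.values())))
    return per_class, macro
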