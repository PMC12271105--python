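"""Instance-segmentation evaluation and model-complexity accounting.

Precision/recall and average precision are computed over mask IoU with
greedy score-descending matching (one ground truth per prediction).  AP
integrates the precision-recall staircase with all-points interpolation
(the precision envelope), and mAP50-95 averages AP over the ten IoU
thresholds 0.5, 0.55, ..., 0.95.

The convolution Params/FLOPs counters follow the usual accounting for a
single conv layer: ``Params = Cin * K^2 * Cout`` (weights only) and
``FLOPs = 2 * H * W * (Cin * K^2 + 1) * Cout`` (the "+1" is the bias
term) — note the two formulas are deliberately kept as commonly printed,
bias excluded from the first and included in the second.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "MatchTable",
    "mask_iou",
    "precision_recall",
    "match_masks",
    "average_precision",
    "map_suite",
    "conv_params",
    "conv_flops",
    "percent_reduction",
]

IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks (0 when both empty)."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    if a.shape != b.shape:
        raise ValueError("masks must share shape")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def precision_recall(tp: int, fp: int, fn: int) -> Tuple[Optional[float], Optional[float]]:
    """P = TP/(TP+FP), R = TP/(TP+FN); undefined ratios come back None."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if (tp + fp) > 0 else None
    r = tp / (tp + fn) if (tp + fn) > 0 else None
    return p, r


@dataclass(frozen=True)
class MatchTable:
    """Score-sorted prediction outcomes against a ground-truth set.

    ``matched[i]`` says whether the i-th highest-scoring prediction was
    assigned a ground-truth instance (greedy, one truth per prediction).
    """

    scores: Tuple[float, ...]
    matched: Tuple[bool, ...]
    n_truth: int

    def __post_init__(self):
        if len(self.scores) != len(self.matched):
            raise ValueError("scores and matched must align")
        if list(self.scores) != sorted(self.scores, reverse=True):
            raise ValueError("MatchTable rows must be sorted by descending score")
        if sum(self.matched) > self.n_truth:
            raise ValueError("more matches than ground-truth instances")

    def counts(self) -> Tuple[int, int, int]:
        tp = int(sum(self.matched))
        return tp, len(self.matched) - tp, self.n_truth - tp


def match_masks(pred_masks: Sequence[np.ndarray], scores: Sequence[float],
                truth_masks: Sequence[np.ndarray],
                iou_threshold: float = 0.5) -> MatchTable:
    """Greedily match predictions to ground truth at one IoU threshold.

    Predictions are visited in descending score order; each takes the
    still-unmatched truth of highest IoU, and counts as a true positive
    when that IoU reaches the threshold.
    """
    if len(pred_masks) != len(scores):
        raise ValueError("one score per prediction required")
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    taken = np.zeros(len(truth_masks), dtype=bool)
    matched: List[bool] = []
    sorted_scores: List[float] = []
    for idx in order:
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truth_masks):
            if taken[j]:
                continue
            iou = mask_iou(pred_masks[idx], t)
            if iou > best_iou:
                best_iou, best_j = iou, j
        ok = best_j >= 0 and best_iou >= iou_threshold
        if ok:
            taken[best_j] = True
        matched.append(ok)
        sorted_scores.append(float(scores[idx]))
    return MatchTable(tuple(sorted_scores), tuple(matched), len(truth_masks))


def average_precision(table: MatchTable) -> float:
    """Area under the precision-recall staircase (all-points interpolation).

    Precision is replaced by its running maximum from the right (the
    envelope) and integrated over the recall increments; invariant to
    any monotone transform of the scores.
    """
    if table.n_truth == 0:
        raise ValueError("average precision undefined without ground truth")
    if not table.matched:
        return 0.0
    tp_cum = np.cumsum(table.matched)
    k = np.arange(1, len(table.matched) + 1)
    precision = tp_cum / k
    recall = tp_cum / table.n_truth
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for p, r in zip(envelope, recall):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def map_suite(pred_masks: Sequence[np.ndarray], scores: Sequence[float],
              truth_masks: Sequence[np.ndarray]) -> Tuple[float, float]:
    """(mAP50, mAP50-95) for the single-class setting.

    With one class the class average degenerates to the class's AP;
    mAP50-95 averages over IoU thresholds 0.5 to 0.95 in steps of 0.05.
    """
    aps = [average_precision(match_masks(pred_masks, scores, truth_masks, thr))
           for thr in IOU_THRESHOLDS]
    return aps[0], float(np.mean(aps))


def conv_params(c_in: int, k: int, c_out: int) -> int:
    """Trainable weight count of one conv layer: Cin * K^2 * Cout."""
    if min(c_in, k, c_out) < 1:
        raise ValueError("channel counts and kernel size must be positive")
    return c_in * k * k * c_out


def conv_flops(h: int, w: int, c_in: int, k: int, c_out: int) -> int:
    """Forward-pass floating point operations of one conv layer:
    2 * H * W * (Cin * K^2 + 1) * Cout."""
    if min(h, w, c_in, k, c_out) < 1:
        raise ValueError("all dimensions must be positive")
    return 2 * h * w * (c_in * k * k + 1) * c_out


def percent_reduction(before: float, after: float) -> float:
    """Relative reduction in percent: 100 * (before - after) / before."""
    if before <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (before - after) / before
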