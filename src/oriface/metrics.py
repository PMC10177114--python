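"""Detection metrics: precision, recall, F1, AP and average angle difference.

Detections are matched to ground truth greedily in descending score order at
IoU 0.5 (each ground-truth box claimed at most once).  Precision, recall and
F1 describe the operating point given by the detector's score threshold; AP
is the area under the full precision-recall sweep (all-points integration
over score thresholds).  The average angle difference (AAD) is the mean
wraparound distance between predicted and true angles over true-positive
matches, in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .angles import angle_distance
from .boxes import iou_matrix
from .inference import Detection

__all__ = ["EvalResult", "match_detections", "pr_ap", "aad", "evaluate_detections"]


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    f1: float
    ap: float
    aad_deg: float  # NaN when no matched pair carries an angle
    tp: int
    fp: int
    fn: int

    def to_dict(self) -> dict:
        return asdict(self)


def match_detections(
    detections: list[Detection],
    gt_boxes: np.ndarray,
    iou_thresh: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy single-image matching.

    Returns (tp_flags, matched_gt) aligned with the detections sorted as
    given; ``matched_gt[i]`` is the claimed ground-truth index for true
    positives and -1 otherwise.  Detections are processed in descending
    score order (index tie-break); a detection is a true positive iff its
    IoU with some still-unclaimed ground truth reaches the threshold.
    """
    n = len(detections)
    tp = np.zeros(n, dtype=bool)
    matched = np.full(n, -1, dtype=np.int64)
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    if n == 0 or gt_boxes.shape[0] == 0:
        return tp, matched
    scores = np.array([d.score for d in detections])
    order = np.lexsort((np.arange(n), -scores))
    det_boxes = np.stack([d.box for d in detections])
    ious = iou_matrix(det_boxes, gt_boxes)
    taken = np.zeros(gt_boxes.shape[0], dtype=bool)
    for i in order:
        row = np.where(taken, -1.0, ious[i])
        g = int(np.argmax(row))
        if row[g] >= iou_thresh:
            tp[i] = True
            matched[i] = g
            taken[g] = True
    return tp, matched


def pr_ap(
    tp_flags: np.ndarray, scores: np.ndarray, n_gt: int
) -> tuple[float, float, float, float, np.ndarray]:
    """Precision/recall/F1 at the operating point plus all-points AP.

    The operating point counts every supplied detection (the caller applies
    its score threshold before matching).  AP sweeps the score from high to
    low and integrates precision over recall increments:
    AP = sum_k (R_k - R_{k-1}) P_k.  Also returns the (recall, precision)
    curve as an (n, 2) array for plotting/export.
    """
    if n_gt <= 0:
        raise ValueError("n_gt must be positive")
    tp_flags = np.asarray(tp_flags, dtype=bool).ravel()
    scores = np.asarray(scores, dtype=np.float64).ravel()
    n = tp_flags.size
    tp_total = int(tp_flags.sum())
    fp_total = n - tp_total
    precision = tp_total / n if n else 0.0
    recall = tp_total / n_gt
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    if n == 0:
        return precision, recall, f1, 0.0, np.zeros((0, 2))
    order = np.lexsort((np.arange(n), -scores))
    cum_tp = np.cumsum(tp_flags[order])
    prec_k = cum_tp / np.arange(1, n + 1)
    rec_k = cum_tp / n_gt
    ap = float(np.sum(np.diff(np.concatenate([[0.0], rec_k])) * prec_k))
    return precision, recall, f1, ap, np.stack([rec_k, prec_k], axis=1)


def aad(pairs: list[tuple[float, float]]) -> float:
    """Average angle difference in degrees over (true, predicted) pairs."""
    if not pairs:
        raise ValueError("AAD is undefined without matched angle pairs")
    return float(np.mean([angle_distance(t, p) for t, p in pairs]) * 180.0)


def evaluate_detections(
    detections_per_image: list[list[Detection]],
    gt_boxes_per_image: list[np.ndarray],
    gt_thetas_per_image: list[np.ndarray] | None = None,
    iou_thresh: float = 0.5,
) -> tuple[EvalResult, np.ndarray]:
    """Corpus-level metrics over per-image detection/ground-truth lists.

    ``gt_thetas_per_image`` may be None (box-only evaluation) or hold, per
    image, an array aligned with that image's ground-truth boxes where NaN
    marks boxes without an angle.  Returns the result plus the PR curve.
    """
    if len(detections_per_image) != len(gt_boxes_per_image):
        raise ValueError("detections and ground truth must align per image")
    all_tp: list[np.ndarray] = []
    all_scores: list[np.ndarray] = []
    angle_pairs: list[tuple[float, float]] = []
    n_gt = 0
    for i, (dets, gts) in enumerate(zip(detections_per_image, gt_boxes_per_image)):
        gts = np.asarray(gts, dtype=np.float64).reshape(-1, 4)
        n_gt += gts.shape[0]
        tp, matched = match_detections(dets, gts, iou_thresh)
        all_tp.append(tp)
        all_scores.append(np.array([d.score for d in dets]))
        if gt_thetas_per_image is not None:
            thetas = np.asarray(gt_thetas_per_image[i], dtype=np.float64).ravel()
            for d_idx, g in enumerate(matched):
                if g >= 0 and g < thetas.size and np.isfinite(thetas[g]):
                    angle_pairs.append((float(thetas[g]), detections_per_image[i][d_idx].theta))
    if n_gt == 0:
        raise ValueError("evaluation needs at least one ground-truth box")
    tp_flags = np.concatenate(all_tp) if all_tp else np.zeros(0, dtype=bool)
    scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
    precision, recall, f1, ap, curve = pr_ap(tp_flags, scores, n_gt)
    tp_total = int(tp_flags.sum())
    result = EvalResult(
        precision=precision,
        recall=recall,
        f1=f1,
        ap=ap,
        aad_deg=aad(angle_pairs) if angle_pairs else float("nan"),
        tp=tp_total,
        fp=int(tp_flags.size - tp_total),
        fn=n_gt - tp_total,
    )
    return result, curve
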