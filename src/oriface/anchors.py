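"""Multi-level anchor grids, anchor-to-ground-truth matching, mini-batch sampling.

Anchors are preset reference boxes tied to the cells of the four pyramid
feature maps.  Each cell carries ``k = len(scale_ratios) * len(aspect_ratios)``
anchor templates (6 by default); the template for scale ``s`` and aspect
``a = w/h`` has ``w = base * s * sqrt(a)`` and ``h = base * s / sqrt(a)``,
i.e. constant area across aspects.  Grid size per level is
``ceil(image_dim / stride)`` and anchor centers sit at cell centers.

The flat anchor ordering is level-major, then row-major over cells, then
template index — the same ordering the detection head uses, so head row *i*
always describes anchor *i*.  At the default 400x400 input and strides
(8, 16, 32, 64) the four grids are 50^2, 25^2, 13^2, 7^2 cells and the flat
list holds 6 * (2500 + 625 + 169 + 49) = 20,058 anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .boxes import center_to_corners, iou_matrix

__all__ = [
    "AnchorSet",
    "generate_anchors",
    "match_anchors",
    "MatchResult",
    "sample_minibatch",
    "DEFAULT_STRIDES",
    "DEFAULT_BASE_SIZES",
    "DEFAULT_SCALE_RATIOS",
    "DEFAULT_ASPECT_RATIOS",
]

DEFAULT_STRIDES = (8, 16, 32, 64)
DEFAULT_BASE_SIZES = (32.0, 64.0, 128.0, 256.0)
DEFAULT_SCALE_RATIOS = (1.0, 2.0)
DEFAULT_ASPECT_RATIOS = (1.0, 2.0, 0.5)

POSITIVE, NEGATIVE, IGNORED = 1, 0, -1


@dataclass(frozen=True)
class AnchorSet:
    """Fixed anchor grid over the feature pyramid for one input size."""

    image_w: int
    image_h: int
    strides: tuple[int, ...]
    grid_sizes: tuple[tuple[int, int], ...]  # (width_cells, height_cells) per level
    anchors_per_cell: int
    centers: np.ndarray  # (A, 4) center-form (x, y, w, h)
    corners: np.ndarray = field(repr=False, default=None)  # (A, 4) corner form

    def __len__(self) -> int:
        return self.centers.shape[0]

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(w * h * self.anchors_per_cell for w, h in self.grid_sizes)


def generate_anchors(
    image_w: int,
    image_h: int,
    strides: tuple[int, ...] = DEFAULT_STRIDES,
    base_sizes: tuple[float, ...] = DEFAULT_BASE_SIZES,
    scale_ratios: tuple[float, ...] = DEFAULT_SCALE_RATIOS,
    aspect_ratios: tuple[float, ...] = DEFAULT_ASPECT_RATIOS,
) -> AnchorSet:
    """Build the flat multi-level anchor list for an ``image_w x image_h`` input."""
    if image_w <= 0 or image_h <= 0:
        raise ValueError("image dimensions must be positive")
    if len(strides) != len(base_sizes):
        raise ValueError("strides and base_sizes must align level-for-level")

    k = len(scale_ratios) * len(aspect_ratios)
    grids: list[tuple[int, int]] = []
    blocks: list[np.ndarray] = []
    for stride, base in zip(strides, base_sizes):
        gw = math.ceil(image_w / stride)
        gh = math.ceil(image_h / stride)
        grids.append((gw, gh))
        # per-cell templates: (k, 2) widths/heights, constant area per scale
        wh = np.array(
            [
                (base * s * math.sqrt(a), base * s / math.sqrt(a))
                for s in scale_ratios
                for a in aspect_ratios
            ]
        )
        cx = (np.arange(gw) + 0.5) * stride
        cy = (np.arange(gh) + 0.5) * stride
        # row-major cells (y outer, x inner), templates innermost
        xx, yy = np.meshgrid(cx, cy)  # (gh, gw)
        cell_centers = np.stack([xx.ravel(), yy.ravel()], axis=1)  # (gh*gw, 2)
        centers = np.repeat(cell_centers, k, axis=0)
        sizes = np.tile(wh, (gh * gw, 1))
        blocks.append(np.concatenate([centers, sizes], axis=1))
    centers = np.concatenate(blocks, axis=0)
    return AnchorSet(
        image_w=image_w,
        image_h=image_h,
        strides=tuple(strides),
        grid_sizes=tuple(grids),
        anchors_per_cell=k,
        centers=centers,
        corners=center_to_corners(centers),
    )


@dataclass(frozen=True)
class MatchResult:
    """Per-anchor labels (positive / negative / ignored) plus matched gt indices."""

    labels: np.ndarray  # (A,) ints in {POSITIVE, NEGATIVE, IGNORED}
    gt_index: np.ndarray  # (A,) int; valid where labels == POSITIVE, else -1

    @property
    def positive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == POSITIVE)

    @property
    def negative_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == NEGATIVE)


def match_anchors(
    anchors: AnchorSet,
    gt_corners: np.ndarray,
    pos_thresh: float = 0.5,
    neg_thresh: float = 0.5,
) -> MatchResult:
    """Assign each anchor to a ground-truth box or to the background.

    An anchor is positive when its best IoU reaches ``pos_thresh`` or when it
    is the highest-IoU anchor for some ground truth (so every object with any
    overlap owns at least one positive); it is negative when its best IoU is
    below ``neg_thresh``; anchors in between are ignored.  Ties break toward
    the lowest anchor / ground-truth index.
    """
    if not 0.0 <= neg_thresh <= pos_thresh <= 1.0:
        raise ValueError("need 0 <= neg_thresh <= pos_thresh <= 1")
    n = len(anchors)
    if n == 0:
        raise ValueError("empty anchor set")
    gt_corners = np.asarray(gt_corners, dtype=np.float64).reshape(-1, 4)
    labels = np.full(n, NEGATIVE, dtype=np.int64)
    gt_index = np.full(n, -1, dtype=np.int64)
    if gt_corners.shape[0] == 0:
        return MatchResult(labels, gt_index)

    ious = iou_matrix(anchors.corners, gt_corners)  # (A, G)
    best_gt = np.argmax(ious, axis=1)  # lowest index on ties
    best_iou = ious[np.arange(n), best_gt]

    labels[(best_iou >= neg_thresh) & (best_iou < pos_thresh)] = IGNORED
    pos = best_iou >= pos_thresh
    labels[pos] = POSITIVE
    gt_index[pos] = best_gt[pos]

    # force the argmax anchor of each gt positive (only if some overlap exists)
    for g in range(gt_corners.shape[0]):
        col = ious[:, g]
        a = int(np.argmax(col))
        if col[a] > 0.0:
            labels[a] = POSITIVE
            gt_index[a] = g
    return MatchResult(labels, gt_index)


def sample_minibatch(
    match: MatchResult,
    size: int = 256,
    pos_fraction: float = 0.25,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a class-balanced anchor mini-batch (Fast R-CNN style).

    Up to ``size * pos_fraction`` positives are drawn; the remainder of the
    budget is filled with negatives.  Returns (positive indices, negative
    indices), each sorted, deterministic for a given rng seed.  The sampled
    positives define N_loc and the full sample defines N_obj in the losses.
    """
    if size <= 0:
        raise ValueError("sample size must be positive")
    if not 0.0 < pos_fraction <= 1.0:
        raise ValueError("pos_fraction must be in (0, 1]")
    rng = np.random.default_rng(rng)
    pos = match.positive_indices
    neg = match.negative_indices
    n_pos = min(len(pos), int(round(size * pos_fraction)))
    if len(pos) > n_pos:
        pos = rng.choice(pos, size=n_pos, replace=False)
    n_neg = min(len(neg), size - len(pos))
    if len(neg) > n_neg:
        neg = rng.choice(neg, size=n_neg, replace=False)
    return np.sort(pos), np.sort(neg)
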