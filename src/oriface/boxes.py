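"""Axis-aligned box arithmetic: corner/center forms, IoU, box encode/decode.

Boxes use a half-open pixel-interval convention: ``[xmin, xmax)`` so that
``width = xmax - xmin``.  Vectorized functions operate on ``(N, 4)`` float
arrays; corner order is ``(xmin, ymin, xmax, ymax)`` and center order is
``(x, y, w, h)``.

The regression coding follows the standard anchor-relative parameterization
with fixed variance-style scale factors 10 (centers) and 5 (log sizes):

    tx = 10 (x - xa) / wa    ty = 10 (y - ya) / ha
    tw = 5 log(w / wa)       th = 5 log(h / ha)

and decoding is its exact inverse.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "corners_to_center",
    "center_to_corners",
    "validate_boxes",
    "iou_matrix",
    "encode_boxes",
    "decode_boxes",
]


def validate_boxes(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    if np.any(boxes[:, 2] <= boxes[:, 0]) or np.any(boxes[:, 3] <= boxes[:, 1]):
        raise ValueError("degenerate box: xmax must exceed xmin and ymax exceed ymin")
    return boxes


def corners_to_center(boxes: np.ndarray) -> np.ndarray:
    """(xmin, ymin, xmax, ymax) -> (x, y, w, h); lossless."""
    boxes = np.asarray(boxes, dtype=np.float64)
    w = boxes[..., 2] - boxes[..., 0]
    h = boxes[..., 3] - boxes[..., 1]
    x = boxes[..., 0] + 0.5 * w
    y = boxes[..., 1] + 0.5 * h
    return np.stack([x, y, w, h], axis=-1)


def center_to_corners(cboxes: np.ndarray) -> np.ndarray:
    """(x, y, w, h) -> (xmin, ymin, xmax, ymax); lossless."""
    cboxes = np.asarray(cboxes, dtype=np.float64)
    hw = 0.5 * cboxes[..., 2]
    hh = 0.5 * cboxes[..., 3]
    return np.stack(
        [
            cboxes[..., 0] - hw,
            cboxes[..., 1] - hh,
            cboxes[..., 0] + hw,
            cboxes[..., 1] + hh,
        ],
        axis=-1,
    )


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise intersection-over-union of corner boxes, shape (len(a), len(b))."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ix0 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy0 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix1 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy1 = np.minimum(a[:, None, 3], b[None, :, 3])
    iw = np.clip(ix1 - ix0, 0.0, None)
    ih = np.clip(iy1 - iy0, 0.0, None)
    inter = iw * ih
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0.0, inter / union, 0.0)
    return out


def encode_boxes(gt_centers: np.ndarray, anchor_centers: np.ndarray) -> np.ndarray:
    """Anchor-relative regression targets (tx, ty, tw, th) for center boxes."""
    g = np.asarray(gt_centers, dtype=np.float64)
    a = np.asarray(anchor_centers, dtype=np.float64)
    tx = 10.0 * (g[..., 0] - a[..., 0]) / a[..., 2]
    ty = 10.0 * (g[..., 1] - a[..., 1]) / a[..., 3]
    tw = 5.0 * np.log(g[..., 2] / a[..., 2])
    th = 5.0 * np.log(g[..., 3] / a[..., 3])
    return np.stack([tx, ty, tw, th], axis=-1)


def decode_boxes(encodings: np.ndarray, anchor_centers: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_boxes`; returns center boxes (x, y, w, h)."""
    t = np.asarray(encodings, dtype=np.float64)
    a = np.asarray(anchor_centers, dtype=np.float64)
    x = t[..., 0] / 10.0 * a[..., 2] + a[..., 0]
    y = t[..., 1] / 10.0 * a[..., 3] + a[..., 1]
    w = a[..., 2] * np.exp(t[..., 2] / 5.0)
    h = a[..., 3] * np.exp(t[..., 3] / 5.0)
    return np.stack([x, y, w, h], axis=-1)
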