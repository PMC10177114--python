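"""From head outputs to detections, and from detections to normalized faces.

Post-processing keeps anchors whose objectness clears a score threshold,
decodes their boxes against the anchor grid, assembles the signed rotation
angle from the direction probability and the absolute angle value, and
applies greedy non-maximum suppression.

Normalization is the system's end purpose: rotate the image by -theta about
the detected box center (bringing the eye line horizontal, left eye on the
left), crop the box, and scale to a square chip for a downstream face
identifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize, rotate

from .anchors import AnchorSet
from .angles import SplitAngle, combine_angle
from .boxes import center_to_corners, decode_boxes, iou_matrix
from .network import DecodedHead

__all__ = ["Detection", "nms", "postprocess", "normalize_face", "NormalizedFace"]


@dataclass(frozen=True)
class Detection:
    """One detected face: corner box, objectness score, signed angle."""

    box: np.ndarray  # (4,) xmin, ymin, xmax, ymax
    score: float
    theta: float

    def to_dict(self) -> dict:
        return {"box": [float(v) for v in self.box], "score": self.score, "theta": self.theta}

    @staticmethod
    def from_dict(d: dict) -> "Detection":
        return Detection(np.asarray(d["box"], dtype=np.float64), float(d["score"]), float(d["theta"]))


@dataclass(frozen=True)
class NormalizedFace:
    """Upright square face chip plus the detection it came from."""

    chip: np.ndarray  # (S, S, C) in [0, 1]
    detection: Detection


def nms(corners: np.ndarray, scores: np.ndarray, iou_thresh: float = 0.5) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, best first.

    Boxes are visited in descending score order (ties broken by lower index)
    and dropped when their IoU with an already-kept box reaches the
    threshold.
    """
    corners = np.asarray(corners, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64).ravel()
    order = np.lexsort((np.arange(len(scores)), -scores))
    keep: list[int] = []
    for i in order:
        if all(iou_matrix(corners[i : i + 1], corners[j : j + 1])[0, 0] < iou_thresh for j in keep):
            keep.append(int(i))
    return np.asarray(keep, dtype=np.int64)


def postprocess(
    decoded: DecodedHead,
    anchors: AnchorSet,
    score_thresh: float = 0.5,
    nms_iou: float = 0.5,
    max_dets: int = 100,
) -> list[Detection]:
    """Threshold, decode, assemble angles, suppress duplicates.

    The signed angle is +value when the counterclockwise probability exceeds
    0.5, else -value.  At most ``max_dets`` detections survive, ordered by
    descending score with deterministic index tie-breaks.
    """
    obj = np.asarray(decoded.objectness, dtype=np.float64).ravel()
    if obj.shape[0] != len(anchors):
        raise ValueError("decoded head and anchor set sizes disagree")
    keep = np.flatnonzero(obj >= score_thresh)
    if keep.size == 0:
        return []
    centers = decode_boxes(decoded.box_encodings[keep], anchors.centers[keep])
    corners = center_to_corners(centers)
    kept = nms(corners, obj[keep], nms_iou)[:max_dets]
    dets = []
    for i in kept:
        a = keep[i]
        theta = combine_angle(SplitAngle(float(decoded.angle_value[a]), decoded.ccw_prob[a] > 0.5))
        dets.append(Detection(box=corners[i], score=float(obj[a]), theta=theta))
    return dets


def normalize_face(image: np.ndarray, det: Detection, out_size: int = 224) -> NormalizedFace:
    """Rotate by -theta about the box center, crop the box, scale to a square.

    The rotation is applied to the whole image first (out-of-bounds regions
    are zero), so rotated content near the box corners is preserved; the
    crop is axis-aligned in the rotated frame with the detection's width and
    height.  Resampling is bilinear.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 2:
        image = image[..., None]
    x0, y0, x1, y1 = det.box
    if x1 <= x0 or y1 <= y0:
        raise ValueError("degenerate detection box")
    cx, cy = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
    # skimage's positive angle is counterclockwise on screen; undoing a CCW
    # rotation by theta half-turns means rotating the image by -theta*180.
    rotated = rotate(
        image, angle=-det.theta * 180.0, center=(cx, cy), order=1, preserve_range=True
    ).astype(np.float32)
    h, w = rotated.shape[:2]
    # integer crop window (half-open), clipped; zero-pad whatever falls outside
    bw, bh = x1 - x0, y1 - y0
    ix0, iy0 = int(np.floor(cx - bw / 2)), int(np.floor(cy - bh / 2))
    ix1, iy1 = int(np.ceil(cx + bw / 2)), int(np.ceil(cy + bh / 2))
    chip = np.zeros((iy1 - iy0, ix1 - ix0, image.shape[2]), dtype=np.float32)
    sx0, sy0 = max(ix0, 0), max(iy0, 0)
    sx1, sy1 = min(ix1, w), min(iy1, h)
    if sx1 > sx0 and sy1 > sy0:
        chip[sy0 - iy0 : sy1 - iy0, sx0 - ix0 : sx1 - ix0] = rotated[sy0:sy1, sx0:sx1]
    chip = resize(
        chip, (out_size, out_size), order=1, mode="edge", anti_aliasing=False, preserve_range=True
    ).astype(np.float32)
    return NormalizedFace(chip=chip, detection=det)
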