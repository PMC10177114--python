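"""Rotation-angle arithmetic for in-plane oriented faces.

The face orientation is the angle between the horizontal axis and the line
running from the left keypoint (left eye) to the right keypoint, measured in
the image plane with the usual image convention: origin at the top-left
corner, x rightward, y downward.  Angles are stored as floats in half-turns,

    theta in (-1.0, 1.0],   theta * 180 = degrees, positive = counterclockwise.

A face whose eye line is horizontal with the left eye on the left has
theta = 0; an upside-down face has theta = 1.  Because theta jumps between
+1 and -1 for nearly upside-down faces, the detector predicts the absolute
value and the direction (sign) separately; :func:`split_angle` and
:func:`combine_angle` convert between the two representations.

All functions accept and return plain floats (or numpy arrays where noted);
every result is canonicalized back into (-1, 1].
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple

import numpy as np

__all__ = [
    "KeypointPair",
    "SplitAngle",
    "wrap_angle",
    "angle_from_keypoints",
    "split_angle",
    "combine_angle",
    "transform_angle",
    "angle_distance",
    "AFFINE_OPS",
]

#: The in-plane augmentation operations with a closed-form angle map.
AFFINE_OPS = ("rot90ccw", "hflip", "vflip")


class KeypointPair(NamedTuple):
    """Left/right keypoint pixel coordinates (distances from the left/top frame)."""

    xl: float
    yl: float
    xr: float
    yr: float

    def swapped(self) -> "KeypointPair":
        """Exchange the left/right labels (what a mirror flip does to a face)."""
        return KeypointPair(self.xr, self.yr, self.xl, self.yl)


class SplitAngle(NamedTuple):
    """Discontinuity-free angle coding: absolute value in [0, 1] plus direction."""

    value: float
    ccw: bool


def wrap_angle(theta: float) -> float:
    """Canonicalize an angle into the half-open interval (-1, 1].

    Exact +1.0 is kept as +1.0 (never mapped to -1.0); -1.0 wraps to +1.0.
    Works on floats and numpy arrays.
    """
    if isinstance(theta, np.ndarray):
        out = np.mod(theta + 1.0, 2.0) - 1.0
        return np.where(out == -1.0, 1.0, out)
    out = math.fmod(theta + 1.0, 2.0)
    if out <= 0.0:
        out += 2.0
    return out - 1.0


def angle_from_keypoints(kp: KeypointPair) -> float:
    """Rotation angle (half-turns) from a left/right keypoint pair.

    With y measured downward, the slope of the eye line is
    k = (yl - yr) / (xr - xl); the angle follows a six-way branch on the
    signs of numerator and denominator, which is exactly
    ``atan2(yl - yr, xr - xl) / pi``.  Branch dispatch through atan2 also
    avoids ever forming an infinite slope when xr == xl.

    Raises
    ------
    ValueError
        If the two keypoints coincide (the angle is undefined).
    """
    dy = kp.yl - kp.yr
    dx = kp.xr - kp.xl
    if dx == 0.0 and dy == 0.0:
        raise ValueError("coincident keypoints: rotation angle is undefined")
    return wrap_angle(math.atan2(dy, dx) / math.pi)


def split_angle(theta: float) -> SplitAngle:
    """Split a signed angle into (absolute value, counterclockwise flag).

    theta == 0 maps to (0, ccw=False) by convention; combine_angle is
    unaffected by the flag in that case.
    """
    return SplitAngle(abs(theta), theta > 0.0)


def combine_angle(s: SplitAngle) -> float:
    """Inverse of :func:`split_angle`; (-1, value 1) canonicalizes to +1.0."""
    return wrap_angle(s.value if s.ccw else -s.value)


def transform_angle(theta: float, op: str) -> float:
    """Ground-truth angle after an in-plane augmentation of the image.

    rot90ccw
        theta + 0.5 if theta <= 0.5, else theta - 1.5 (i.e. wrap(theta + 0.5)).
    hflip
        -theta.  A horizontal mirror reverses the rotation direction (and
        swaps which eye is the face's left one).
    vflip
        wrap(1 - theta).  For theta >= 0 this is the familiar 1 - theta; for
        theta < 0 it wraps to -1 - theta, keeping the sign-flip a mirror
        implies.  This is the unique map consistent with the keypoint
        relabeling a vertical mirror performs: it is an involution, and
        composing it with hflip gives an exact 180-degree rotation
        (wrap(theta + 1)), as it must.
    """
    if op == "rot90ccw":
        out = theta + 0.5 if theta <= 0.5 else theta - 1.5
    elif op == "hflip":
        out = -theta
    elif op == "vflip":
        out = 1.0 - theta
    else:
        raise ValueError(f"unknown angle transform {op!r}")
    return wrap_angle(out)


def angle_distance(theta_true: float, theta_pred: float) -> float:
    """Wraparound distance between two canonical angles, in half-turns [0, 1].

    D = |t* - t| if |t* - t| < 1 else 2 - |t* - t|, so nearly-upside-down
    faces coded +0.99 and -0.99 are 0.02 apart, not 1.98.
    """
    d = abs(theta_true - theta_pred)
    return d if d < 1.0 else 2.0 - d


def mean_angle_distance(pairs: Iterable[tuple[float, float]]) -> float:
    """Mean wraparound distance over (true, predicted) pairs, in half-turns."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("mean_angle_distance needs at least one pair")
    return float(np.mean([angle_distance(t, p) for t, p in pairs]))
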