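"""Synthetic oriented-face scenes with exact ground truth.

Each scene is a flat background holding one or more "face" glyphs: a filled
ellipse with two darker eye dots placed symmetrically about the face axis,
rigidly rotated by an angle drawn uniformly from (-1, 1] half-turns.  For
every glyph the generator records the exact axis-aligned bounding box of the
ellipse, the rotation angle, and the two eye keypoints — so the whole
detection/normalization/evaluation stack can be exercised with known answers
and no external data.

The glyphs emulate the salient structure of the real use case (a compact
face-like blob whose eye line defines the orientation) but none of the
photographic nuisance of field imagery: no occlusion, background clutter,
lighting variation or pose change beyond in-plane rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .angles import KeypointPair, wrap_angle
from .data import AnnotatedImage, FaceRecord

__all__ = ["SyntheticSceneSpec", "generate_scene", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Study conditions for the synthetic scenes.

    Sizes are in pixels on a square canvas.  ``face_radius`` bounds the
    ellipse semi-minor axis a (the eye-line direction); the perpendicular
    semi-axis is ``elongation * a``, giving a slightly oblong face.  Angles
    are uniform on (-1, 1] half-turns.  ``noise_std`` is additive Gaussian
    pixel noise on a [0, 1] intensity scale.
    """

    size: int = 128
    channels: int = 1
    faces_min: int = 1
    faces_max: int = 2
    face_radius: tuple[float, float] = (14.0, 26.0)
    elongation: float = 1.3
    noise_std: float = 0.02
    background: float = 0.10
    face_intensity: float = 0.85
    eye_intensity: float = 0.25

    def __post_init__(self):
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        if self.faces_min < 1 or self.faces_max < self.faces_min:
            raise ValueError("need 1 <= faces_min <= faces_max")
        a_max = self.face_radius[1] * self.elongation
        if 2 * a_max >= self.size:
            raise ValueError("largest glyph cannot fit the canvas")


# eye geometry relative to the upright glyph (fractions of the semi-axes)
_EYE_X = 0.45  # along the eye line, fraction of a
_EYE_Y = -0.35  # above center (screen up = negative y), fraction of b
_EYE_R = 0.16  # eye radius, fraction of a


def _rotation(theta: float) -> np.ndarray:
    """Screen-coordinate (y down) rotation by theta half-turns CCW."""
    phi = theta * math.pi
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, s], [-s, c]])


def _render_glyph(
    canvas: np.ndarray, center: np.ndarray, a: float, b: float, theta: float, spec: SyntheticSceneSpec
) -> FaceRecord:
    rot = _rotation(theta)
    h, w = canvas.shape[:2]
    c_phi, s_phi = rot[0, 0], rot[0, 1]
    half_w = math.hypot(a * c_phi, b * s_phi)
    half_h = math.hypot(a * s_phi, b * c_phi)
    x0, x1 = center[0] - half_w, center[0] + half_w
    y0, y1 = center[1] - half_h, center[1] + half_h

    # pixel-center coordinates of the enclosing window
    ix0, ix1 = max(0, int(math.floor(x0))), min(w, int(math.ceil(x1)) + 1)
    iy0, iy1 = max(0, int(math.floor(y0))), min(h, int(math.ceil(y1)) + 1)
    xs = np.arange(ix0, ix1) + 0.5
    ys = np.arange(iy0, iy1) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    qx = gx - center[0]
    qy = gy - center[1]
    # unrotate the offset: R^T q
    px = rot[0, 0] * qx + rot[1, 0] * qy
    py = rot[0, 1] * qx + rot[1, 1] * qy
    inside = (px / a) ** 2 + (py / b) ** 2 <= 1.0
    window = canvas[iy0:iy1, ix0:ix1]
    window[inside] = spec.face_intensity

    eye_r = max(1.2, _EYE_R * a)
    eyes = []
    for sign in (-1.0, 1.0):
        offset = rot @ np.array([sign * _EYE_X * a, _EYE_Y * b])
        eye = center + offset
        eyes.append(eye)
        d2 = (gx - eye[0]) ** 2 + (gy - eye[1]) ** 2
        window[d2 <= eye_r**2] = spec.eye_intensity
    left, right = eyes
    kp = KeypointPair(float(left[0]), float(left[1]), float(right[0]), float(right[1]))
    return FaceRecord(box=np.array([x0, y0, x1, y1]), theta=theta, keypoints=kp)


def generate_scene(
    spec: SyntheticSceneSpec = SyntheticSceneSpec(),
    rng: np.random.Generator | int | None = None,
    dataset_tag: str = "ds1",
) -> AnnotatedImage:
    """Render one scene; glyph boxes avoid overlapping each other."""
    rng = np.random.default_rng(rng)
    size = spec.size
    canvas = np.full((size, size), spec.background, dtype=np.float64)
    n_faces = int(rng.integers(spec.faces_min, spec.faces_max + 1))
    records: list[FaceRecord] = []
    placed: list[tuple[np.ndarray, float]] = []  # (center, clearance radius)
    for _ in range(n_faces):
        for _attempt in range(50):
            a = float(rng.uniform(*spec.face_radius))
            b = spec.elongation * a
            theta = wrap_angle(float(rng.uniform(-1.0, 1.0)))
            margin = b + 1.0
            center = rng.uniform(margin, size - margin, size=2)
            if all(np.linalg.norm(center - c0) > b + r0 + 2.0 for c0, r0 in placed):
                records.append(_render_glyph(canvas, center, a, b, theta, spec))
                placed.append((center, b))
                break
        # if 50 placements all collide the face is skipped (crowded small canvas)
    if spec.noise_std > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_std, canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0).astype(np.float32)[..., None]
    if spec.channels == 3:
        canvas = np.repeat(canvas, 3, axis=2)
    if dataset_tag == "ds2":
        records = [FaceRecord(box=r.box.copy()) for r in records]
    return AnnotatedImage(image=canvas, records=records, dataset_tag=dataset_tag)


def generate_dataset(
    n: int,
    spec: SyntheticSceneSpec = SyntheticSceneSpec(),
    seed: int = 0,
    dataset_tag: str = "ds1",
) -> list[AnnotatedImage]:
    """Generate ``n`` scenes reproducibly from a single seed."""
    rng = np.random.default_rng(seed)
    return [generate_scene(spec, rng, dataset_tag) for _ in range(n)]
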