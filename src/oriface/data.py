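"""Annotated images, JSONL annotation I/O, angle-aware augmentation, batching.

Two kinds of training data coexist: angle-labeled images ("ds1", every face
carries a rotation angle or an eye keypoint pair it can be computed from) and
box-only images ("ds2").  The batcher mixes T1 images of the first kind with
T2 of the second in every training batch, tagging each image with its origin
so the losses can mask angle terms for box-only data.

Augmentations are the three closed-form affine ops (90 degree rotation,
horizontal/vertical flip), each transforming pixels, boxes, keypoints and
angles consistently, plus 2x2 / 3x3 image tiling which concatenates several
scenes into one (boxes scaled, angles untouched because the scaling is
isotropic).  Affine ops are applied per image first, then tiling, then
letterboxing to the network input size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .angles import KeypointPair, angle_from_keypoints, transform_angle, wrap_angle

__all__ = [
    "FaceRecord",
    "AnnotatedImage",
    "OpProbabilities",
    "AugmentationConfig",
    "read_annotations",
    "write_annotations",
    "augment",
    "tile",
    "letterbox",
    "DualBatcher",
]


@dataclass
class FaceRecord:
    """One ground-truth face: corner box, optional angle and/or eye keypoints."""

    box: np.ndarray  # (4,) xmin, ymin, xmax, ymax
    theta: float | None = None
    keypoints: KeypointPair | None = None

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.box.shape != (4,):
            raise ValueError("box must be (xmin, ymin, xmax, ymax)")
        if self.box[2] <= self.box[0] or self.box[3] <= self.box[1]:
            raise ValueError(f"degenerate box {self.box.tolist()}")
        if self.theta is None and self.keypoints is not None:
            self.theta = angle_from_keypoints(self.keypoints)


@dataclass
class AnnotatedImage:
    """Image array (H, W, C) in [0, 1] plus its face records and dataset tag."""

    image: np.ndarray
    records: list[FaceRecord]
    dataset_tag: str = "ds1"

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim == 2:
            self.image = self.image[..., None]
        if self.image.ndim != 3 or self.image.shape[2] not in (1, 3):
            raise ValueError("image must be (H, W, C) with C in {1, 3}")
        if self.dataset_tag not in ("ds1", "ds2"):
            raise ValueError(f"dataset_tag must be 'ds1' or 'ds2', got {self.dataset_tag!r}")
        if self.dataset_tag == "ds1":
            for i, rec in enumerate(self.records):
                if rec.theta is None:
                    raise ValueError(f"ds1 record {i} lacks both angle and keypoints")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.image.shape

    def gt_boxes(self) -> np.ndarray:
        if not self.records:
            return np.zeros((0, 4))
        return np.stack([r.box for r in self.records])


# ---------------------------------------------------------------------------
# annotation serialization (JSON lines, one record per image)
# ---------------------------------------------------------------------------

def write_annotations(path: str | Path, images: list[AnnotatedImage], image_dir: str | Path | None = None) -> None:
    """Write a JSONL annotation file; image pixels go to PNGs under image_dir.

    If ``image_dir`` is None only the annotations are written (records carry
    ``"image": null``) — useful when pixels live elsewhere.
    """
    import os

    path = Path(path)
    if image_dir is not None:
        image_dir = Path(image_dir)
        image_dir.mkdir(parents=True, exist_ok=True)
        # records point at images relative to the annotation file itself
        rel_dir = os.path.relpath(image_dir, path.parent)
    with open(path, "w") as fh:
        for i, ann in enumerate(images):
            name = None
            if image_dir is not None:
                fname = f"img_{i:06d}.png"
                save_image(image_dir / fname, ann.image)
                name = str(Path(rel_dir) / fname) if rel_dir != "." else fname
            h, w, c = ann.shape
            objects = []
            for rec in ann.records:
                obj: dict = {"box": [float(v) for v in rec.box]}
                if rec.theta is not None:
                    obj["theta"] = float(rec.theta)
                if rec.keypoints is not None:
                    obj["keypoints"] = [float(v) for v in rec.keypoints]
                objects.append(obj)
            fh.write(
                json.dumps(
                    {
                        "image": name,
                        "width": w,
                        "height": h,
                        "channels": c,
                        "dataset": ann.dataset_tag,
                        "objects": objects,
                    }
                )
                + "\n"
            )


def read_annotations(path: str | Path, image_dir: str | Path | None = None) -> list[AnnotatedImage]:
    """Read a JSONL annotation file back into AnnotatedImages.

    Keypoint pairs without an explicit angle get their angle computed on
    load.  Malformed records raise with the offending line number.
    """
    path = Path(path)
    image_dir = Path(image_dir) if image_dir is not None else path.parent
    out: list[AnnotatedImage] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                records = []
                for obj in rec["objects"]:
                    kp = obj.get("keypoints")
                    records.append(
                        FaceRecord(
                            box=np.asarray(obj["box"], dtype=np.float64),
                            theta=obj.get("theta"),
                            keypoints=KeypointPair(*kp) if kp is not None else None,
                        )
                    )
                if rec["image"] is not None:
                    # names are relative to the annotation file; an explicit
                    # image_dir is the fallback for relocated images
                    candidate = path.parent / rec["image"]
                    if not candidate.exists():
                        candidate = image_dir / Path(rec["image"]).name
                    image = load_image(candidate)
                else:
                    image = np.zeros((rec["height"], rec["width"], rec["channels"]), dtype=np.float32)
                out.append(AnnotatedImage(image=image, records=records, dataset_tag=rec["dataset"]))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed annotation record: {exc}") from exc
    return out


def save_image(path: str | Path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image, dtype=np.float32), 0.0, 1.0)
    arr8 = np.round(arr * 255.0).astype(np.uint8)
    if arr8.shape[-1] == 1:
        Image.fromarray(arr8[..., 0], mode="L").save(path)
    else:
        Image.fromarray(arr8, mode="RGB").save(path)


def load_image(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=np.float32) / 255.0
    if arr.ndim == 2:
        arr = arr[..., None]
    return arr


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _transform_record(rec: FaceRecord, op: str, w: float, h: float) -> FaceRecord:
    x0, y0, x1, y1 = rec.box
    kp = rec.keypoints
    if op == "rot90ccw":
        box = np.array([y0, w - x1, y1, w - x0])
        new_kp = KeypointPair(kp.yl, w - kp.xl, kp.yr, w - kp.xr) if kp else None
    elif op == "hflip":
        box = np.array([w - x1, y0, w - x0, y1])
        # a mirror swaps which eye is the face's left one
        new_kp = KeypointPair(w - kp.xl, kp.yl, w - kp.xr, kp.yr).swapped() if kp else None
    elif op == "vflip":
        box = np.array([x0, h - y1, x1, h - y0])
        new_kp = KeypointPair(kp.xl, h - kp.yl, kp.xr, h - kp.yr).swapped() if kp else None
    else:
        raise ValueError(f"unknown augmentation op {op!r}")
    theta = transform_angle(rec.theta, op) if rec.theta is not None else None
    return FaceRecord(box=box, theta=theta, keypoints=new_kp)


def augment(ann: AnnotatedImage, op: str) -> AnnotatedImage:
    """Apply one affine op to pixels, boxes, keypoints and angles consistently."""
    h, w, _ = ann.shape
    if op == "rot90ccw":
        image = np.ascontiguousarray(np.rot90(ann.image, 1, axes=(0, 1)))
    elif op == "hflip":
        image = np.ascontiguousarray(ann.image[:, ::-1])
    elif op == "vflip":
        image = np.ascontiguousarray(ann.image[::-1])
    else:
        raise ValueError(f"unknown augmentation op {op!r}")
    records = [_transform_record(r, op, w, h) for r in ann.records]
    return AnnotatedImage(image=image, records=records, dataset_tag=ann.dataset_tag)


def _resize(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    from skimage.transform import resize

    return resize(
        image, (out_h, out_w), order=1, mode="edge", anti_aliasing=False, preserve_range=True
    ).astype(np.float32)


def tile(images: list[AnnotatedImage], layout: str = "2x2") -> AnnotatedImage:
    """Concatenate 4 (2x2) or 9 (3x3) scenes into one; angles are unchanged.

    Each source is resized to one grid cell of the first image's canvas.
    Boxes and keypoints are scaled with the same (isotropic for equal-sized
    sources) factors and offset to their cell.
    """
    n_side = {"2x2": 2, "3x3": 3}.get(layout)
    if n_side is None:
        raise ValueError("layout must be '2x2' or '3x3'")
    if len(images) != n_side * n_side:
        raise ValueError(f"{layout} tiling needs {n_side * n_side} images, got {len(images)}")
    channels = {ann.shape[2] for ann in images}
    if len(channels) != 1:
        raise ValueError("tiled images must share the channel count")
    h0, w0, c = images[0].shape
    ch, cw = h0 // n_side, w0 // n_side
    canvas = np.zeros((ch * n_side, cw * n_side, c), dtype=np.float32)
    records: list[FaceRecord] = []
    for idx, ann in enumerate(images):
        row, col = divmod(idx, n_side)
        oy, ox = row * ch, col * cw
        h, w, _ = ann.shape
        sy, sx = ch / h, cw / w
        canvas[oy : oy + ch, ox : ox + cw] = _resize(ann.image, ch, cw)
        for rec in ann.records:
            box = rec.box * np.array([sx, sy, sx, sy]) + np.array([ox, oy, ox, oy])
            kp = rec.keypoints
            new_kp = (
                KeypointPair(kp.xl * sx + ox, kp.yl * sy + oy, kp.xr * sx + ox, kp.yr * sy + oy)
                if kp
                else None
            )
            records.append(FaceRecord(box=box, theta=rec.theta, keypoints=new_kp))
    return AnnotatedImage(image=canvas, records=records, dataset_tag=images[0].dataset_tag)


def letterbox(ann: AnnotatedImage, size: int) -> AnnotatedImage:
    """Isotropically scale into a size x size canvas, zero-padding the rest.

    Angles are untouched (the scale is isotropic); boxes and keypoints are
    scaled by the common factor.  The image is anchored at the top-left.
    """
    h, w, c = ann.shape
    if h == w == size:
        return ann
    scale = min(size / h, size / w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    canvas = np.zeros((size, size, c), dtype=np.float32)
    canvas[:nh, :nw] = _resize(ann.image, nh, nw)
    sx, sy = nw / w, nh / h
    records = []
    for rec in ann.records:
        box = rec.box * np.array([sx, sy, sx, sy])
        kp = rec.keypoints
        new_kp = KeypointPair(kp.xl * sx, kp.yl * sy, kp.xr * sx, kp.yr * sy) if kp else None
        records.append(FaceRecord(box=box, theta=rec.theta, keypoints=new_kp))
    return AnnotatedImage(image=canvas, records=records, dataset_tag=ann.dataset_tag)


# ---------------------------------------------------------------------------
# dual-dataset batching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpProbabilities:
    """Per-operation trigger probabilities; the ops fire independently."""

    rot90ccw: float = 0.5
    hflip: float = 0.5
    vflip: float = 0.5
    tile2x2: float = 0.8
    tile3x3: float = 0.0

    def __post_init__(self):
        for name, p in vars(self).items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")


@dataclass(frozen=True)
class AugmentationConfig:
    """Batch composition and augmentation schedule for dual-dataset training."""

    ds1: OpProbabilities = field(default_factory=OpProbabilities)
    ds2: OpProbabilities = field(
        default_factory=lambda: OpProbabilities(rot90ccw=0.0, hflip=0.5, vflip=0.5, tile2x2=0.8)
    )
    t1: int = 7  # images per batch from the angle-labeled dataset
    t2: int = 5  # images per batch from the box-only dataset

    def __post_init__(self):
        if self.t1 < 0 or self.t2 < 0 or self.t1 + self.t2 == 0:
            raise ValueError("batch sizes must be non-negative and sum to > 0")


class _Stream:
    """Reshuffle-and-repeat iterator over a dataset (epoch boundaries hidden)."""

    def __init__(self, items: list[AnnotatedImage], tag: str, rng: np.random.Generator):
        if not items:
            raise ValueError("dataset stream must be non-empty")
        self.items = items
        self.tag = tag
        self.rng = rng
        self._order: list[int] = []

    def next(self) -> AnnotatedImage:
        if not self._order:
            self._order = list(self.rng.permutation(len(self.items)))
        ann = self.items[self._order.pop()]
        if ann.dataset_tag != self.tag:
            ann = replace(ann, dataset_tag=self.tag)
        return ann


class DualBatcher:
    """Draws T1 angle-labeled + T2 box-only images per batch, augmented.

    Per drawn image each affine op fires independently with its configured
    probability; then, with the tiling probability, 3 (or 8) further draws
    from the same stream are merged into one mosaic.  Finally every image is
    letterboxed to ``input_size``.  Fully deterministic given the seed.
    """

    def __init__(
        self,
        ds1: list[AnnotatedImage],
        ds2: list[AnnotatedImage] | None,
        cfg: AugmentationConfig = AugmentationConfig(),
        input_size: int = 400,
        seed: int = 0,
    ):
        self.cfg = cfg
        self.input_size = input_size
        self.rng = np.random.default_rng(seed)
        self._s1 = _Stream(ds1, "ds1", self.rng)
        # the box-only dataset may alias the angle-labeled one
        self._s2 = _Stream(ds2 if ds2 is not None else ds1, "ds2", self.rng)

    def _draw_one(self, stream: _Stream, probs: OpProbabilities) -> AnnotatedImage:
        ann = stream.next()
        for op in ("rot90ccw", "hflip", "vflip"):
            if self.rng.random() < getattr(probs, op):
                ann = augment(ann, op)
        return ann

    def _draw_slot(self, stream: _Stream, probs: OpProbabilities) -> AnnotatedImage:
        ann = self._draw_one(stream, probs)
        layout = None
        if self.rng.random() < probs.tile3x3:
            layout = "3x3"
        elif self.rng.random() < probs.tile2x2:
            layout = "2x2"
        if layout is not None:
            extra = {"2x2": 3, "3x3": 8}[layout]
            group = [ann] + [self._draw_one(stream, probs) for _ in range(extra)]
            ann = tile(group, layout)
        return letterbox(ann, self.input_size)

    def next_batch(self) -> list[AnnotatedImage]:
        batch = [self._draw_slot(self._s1, self.cfg.ds1) for _ in range(self.cfg.t1)]
        batch += [self._draw_slot(self._s2, self.cfg.ds2) for _ in range(self.cfg.t2)]
        return batch

    def get_state(self) -> dict:
        """Serializable draw state (for exact training resume)."""
        return {
            "rng": self.rng.bit_generator.state,
            "order1": [int(i) for i in self._s1._order],
            "order2": [int(i) for i in self._s2._order],
        }

    def set_state(self, state: dict) -> None:
        self.rng.bit_generator.state = state["rng"]
        self._s1._order = list(state["order1"])
        self._s2._order = list(state["order2"])
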