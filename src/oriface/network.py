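"""Detector network: lightweight CBA backbone, top-down neck, shared dense head.

The backbone is 14 convolution/batch-norm/ReLU (CBA) units in five blocks:
block 1 holds two CBA (the first with a 7x7 kernel, stride 2), blocks 2-5
hold three CBA each with 3x3 kernels, the first at stride 2 and the third
with four times the channels of the first two.  The last CBA of blocks 3-5
feeds the neck at strides 8, 16 and 32.

The neck maps those three tensors to a common channel width with 1x1 lateral
convolutions, merges them top-down (nearest 2x up-sampling + addition,
cropping when ceil-divided sizes differ by one), and appends a fourth,
stride-64 map via a stride-2 convolution — four uniform-width feature maps.

One shared 3x3 convolution turns every map into k*9 channels (54 for the
default k = 6 anchors per cell): per anchor 2 objectness logits, 4 box
encodings, 2 direction logits, 1 angle-value logit.  Flattening is row-major
over cells with templates innermost and levels concatenated shallow to deep,
matching the flat anchor ordering exactly: head row i describes anchor i.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import anchors as anchor_mod
from .anchors import AnchorSet, generate_anchors
from .nn import CBA, Conv2d, Module, Tensor, concat, upsample2x

__all__ = [
    "NetworkConfig",
    "Backbone",
    "Neck",
    "DetectionNetwork",
    "DecodedHead",
    "decode_head",
    "save_checkpoint",
    "load_checkpoint",
]

HEAD_VALUES_PER_ANCHOR = 9
# head column layout
OBJ_SLICE = slice(0, 2)
BOX_SLICE = slice(2, 6)
DIR_SLICE = slice(6, 8)
ANGLE_COL = 8


@dataclass
class NetworkConfig:
    input_channels: int = 3
    input_size: int = 400
    base_width: int = 16
    neck_width: int = 64
    head_kernel: int = 3
    anchors_per_cell: int = 6
    strides: tuple[int, ...] = anchor_mod.DEFAULT_STRIDES
    base_sizes: tuple[float, ...] = anchor_mod.DEFAULT_BASE_SIZES
    scale_ratios: tuple[float, ...] = anchor_mod.DEFAULT_SCALE_RATIOS
    aspect_ratios: tuple[float, ...] = anchor_mod.DEFAULT_ASPECT_RATIOS
    seed: int = 0

    def __post_init__(self):
        if self.input_channels not in (1, 3):
            raise ValueError("input_channels must be 1 (grayscale/infrared) or 3 (RGB)")
        k = len(self.scale_ratios) * len(self.aspect_ratios)
        if self.anchors_per_cell != k:
            raise ValueError(
                f"anchors_per_cell={self.anchors_per_cell} inconsistent with "
                f"{len(self.scale_ratios)} scales x {len(self.aspect_ratios)} aspects"
            )

    def make_anchors(self, image_w: int | None = None, image_h: int | None = None) -> AnchorSet:
        w = image_w or self.input_size
        h = image_h or self.input_size
        return generate_anchors(
            w, h, self.strides, self.base_sizes, self.scale_ratios, self.aspect_ratios
        )


class Backbone(Module):
    """Five-block, 14-CBA feature extractor emitting stride-8/16/32 tensors."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        w = cfg.base_width
        self.block1 = [
            CBA(cfg.input_channels, w, kernel=7, stride=2, rng=rng),
            CBA(w, w, kernel=3, stride=1, rng=rng),
        ]
        blocks = []
        in_ch = w
        self.out_channels: list[int] = []
        for b in range(4):  # blocks 2..5
            width = w * (2 ** (b + 1))
            blocks.append(
                [
                    CBA(in_ch, width, kernel=3, stride=2, rng=rng),
                    CBA(width, width, kernel=3, stride=1, rng=rng),
                    CBA(width, 4 * width, kernel=3, stride=1, rng=rng),
                ]
            )
            in_ch = 4 * width
            self.out_channels.append(in_ch)
        self.block2, self.block3, self.block4, self.block5 = blocks

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        for cba in self.block1 + self.block2:
            x = cba(x)
        for cba in self.block3:
            x = cba(x)
        c3 = x  # stride 8
        for cba in self.block4:
            x = cba(x)
        c4 = x  # stride 16
        for cba in self.block5:
            x = cba(x)
        return c3, c4, x  # strides 8, 16, 32


class Neck(Module):
    """Top-down pyramid: laterals, 2x up-sample + add, extra stride-64 level."""

    def __init__(self, in_channels: list[int], width: int, rng: np.random.Generator):
        self.lateral3 = Conv2d(in_channels[0], width, kernel=1, rng=rng)
        self.lateral4 = Conv2d(in_channels[1], width, kernel=1, rng=rng)
        self.lateral5 = Conv2d(in_channels[2], width, kernel=1, rng=rng)
        self.down6 = Conv2d(width, width, kernel=3, stride=2, rng=rng)

    def __call__(self, c3: Tensor, c4: Tensor, c5: Tensor) -> list[Tensor]:
        p5 = self.lateral5(c5)
        l4 = self.lateral4(c4)
        p4 = l4 + upsample2x(p5, l4.shape[1], l4.shape[2])
        l3 = self.lateral3(c3)
        p3 = l3 + upsample2x(p4, l3.shape[1], l3.shape[2])
        p6 = self.down6(p5)
        return [p3, p4, p5, p6]  # shallow -> deep, strides 8/16/32/64


class DetectionNetwork(Module):
    """Full detector: image batch (N, H, W, C) -> head tensor (N, A, 9)."""

    def __init__(self, cfg: NetworkConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.backbone = Backbone(cfg, rng)
        self.neck = Neck(self.backbone.out_channels[1:], cfg.neck_width, rng)
        self.head = Conv2d(
            cfg.neck_width,
            cfg.anchors_per_cell * HEAD_VALUES_PER_ANCHOR,
            kernel=cfg.head_kernel,
            rng=rng,
        )

    def __call__(self, images: np.ndarray | Tensor) -> Tensor:
        x = images if isinstance(images, Tensor) else Tensor(images)
        if x.data.ndim != 4 or x.data.shape[3] != self.cfg.input_channels:
            raise ValueError(
                f"expected (N, H, W, {self.cfg.input_channels}) input, got {x.data.shape}"
            )
        maps = self.neck(*self.backbone(x))
        outs = []
        n = x.data.shape[0]
        for fmap in maps:
            h = self.head(fmap)  # (N, H, W, k*9)
            outs.append(h.reshape(n, -1, HEAD_VALUES_PER_ANCHOR))
        return concat(outs, axis=1)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


@dataclass
class DecodedHead:
    """Per-anchor probabilities and raw box encodings, all plain numpy."""

    objectness: np.ndarray  # (..., A) probability the anchor holds a face
    box_encodings: np.ndarray  # (..., A, 4)
    ccw_prob: np.ndarray  # (..., A) probability of counterclockwise rotation
    angle_value: np.ndarray  # (..., A) absolute angle in (0, 1) half-turns


def _softmax2(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def decode_head(head: np.ndarray) -> DecodedHead:
    """Turn raw head values into probabilities (softmax) and angle values (sigmoid)."""
    head = np.asarray(head, dtype=np.float64)
    obj = _softmax2(head[..., OBJ_SLICE])[..., 1]
    ccw = _softmax2(head[..., DIR_SLICE])[..., 1]
    value = 1.0 / (1.0 + np.exp(-head[..., ANGLE_COL]))
    return DecodedHead(
        objectness=obj,
        box_encodings=head[..., BOX_SLICE],
        ccw_prob=ccw,
        angle_value=value,
    )


CHECKPOINT_VERSION = 1


def save_checkpoint(
    path: str | Path,
    model: DetectionNetwork,
    extra: dict | None = None,
    extra_arrays: dict[str, np.ndarray] | None = None,
) -> None:
    """Single-file .npz checkpoint: config JSON + all parameter/buffer arrays.

    ``extra`` must be JSON-serializable; ``extra_arrays`` keys must start
    with ``__`` so they never collide with model state names.
    """
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(model.cfg), "extra": extra or {}}
    arrays = dict(model.state_arrays())
    for key, value in (extra_arrays or {}).items():
        if not key.startswith("__"):
            raise ValueError(f"extra array name must start with '__': {key}")
        arrays[key] = value
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path, with_arrays: bool = False):
    """Load a checkpoint into a fresh eval-mode model.

    Returns ``(model, extra)`` or, with ``with_arrays=True``,
    ``(model, extra, extra_arrays)``.
    """
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        cfg_dict = meta["config"]
        for key in ("strides", "base_sizes", "scale_ratios", "aspect_ratios"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = DetectionNetwork(NetworkConfig(**cfg_dict))
        state = {k: data[k] for k in data.files if not k.startswith("__")}
        extras = {k: data[k] for k in data.files if k.startswith("__") and k != "__meta__"}
    model.load_state_arrays(state)
    model.set_training(False)  # checkpoints load inference-ready
    if with_arrays:
        return model, meta["extra"], extras
    return model, meta["extra"]
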