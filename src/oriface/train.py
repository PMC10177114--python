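"""Training: target assembly, the four-term objective on head outputs, SGD loop.

One training step draws a dual-dataset batch, runs the network forward,
matches anchors to ground truth and samples a class-balanced anchor
mini-batch per image, evaluates the weighted four-term loss on the sampled
head rows, backpropagates and takes a momentum-SGD step on a cosine-decayed
learning rate.  Everything is deterministic for a given config seed on one
device.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .anchors import AnchorSet, match_anchors, sample_minibatch
from .boxes import corners_to_center, encode_boxes
from .data import AnnotatedImage, AugmentationConfig, DualBatcher
from .inference import Detection, postprocess
from .losses import (
    LossBreakdown,
    LossWeights,
    angle_direction_loss,
    angle_value_loss,
    localization_loss,
    objectness_loss,
    total_loss,
)
from .network import (
    ANGLE_COL,
    BOX_SLICE,
    DIR_SLICE,
    OBJ_SLICE,
    DetectionNetwork,
    NetworkConfig,
    decode_head,
    load_checkpoint,
    save_checkpoint,
)
from .nn import SGD, Tensor

__all__ = ["TrainConfig", "BatchTargets", "build_targets", "training_loss", "train", "detect_images"]


@dataclass
class TrainConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    total_steps: int = 50_000
    learning_rate: float = 0.01
    momentum: float = 0.9
    final_lr_fraction: float = 0.01  # cosine decay floor as a fraction of learning_rate
    warmup_steps: int = 50  # linear ramp from 0 avoids early divergence
    clip_grad_norm: float = 10.0  # global-norm gradient clipping; 0 disables
    sampler_size: int = 256
    sampler_pos_fraction: float = 0.25
    match_pos_thresh: float = 0.5
    match_neg_thresh: float = 0.5
    checkpoint_every: int = 0  # 0 = only at the end
    seed: int = 0

    def __post_init__(self):
        if self.total_steps <= 0:
            raise ValueError("total_steps must be positive")

    def lr_at(self, step: int) -> float:
        """Linear warmup, then cosine decay to learning_rate * final_lr_fraction."""
        if self.warmup_steps > 0 and step < self.warmup_steps:
            return self.learning_rate * (step + 1) / self.warmup_steps
        t = (step - self.warmup_steps) / max(1, self.total_steps - 1 - self.warmup_steps)
        lo = self.learning_rate * self.final_lr_fraction
        return lo + 0.5 * (self.learning_rate - lo) * (1.0 + math.cos(math.pi * min(t, 1.0)))


@dataclass
class BatchTargets:
    """Flat (over image x anchor) index sets and targets for one batch."""

    sampled_indices: np.ndarray  # (N_obj,) indices into the flattened head
    sampled_labels: np.ndarray  # (N_obj,) {0, 1} objectness
    positive_indices: np.ndarray  # (N_loc,) indices into the flattened head
    box_targets: np.ndarray  # (N_loc, 4) encodings
    angle_values: np.ndarray  # (N_loc,) |theta*|; 0 for box-only images
    ccw_labels: np.ndarray  # (N_loc,) {0, 1}
    ds_tags: np.ndarray  # (N_loc,) "ds1"/"ds2"
    gate_values: np.ndarray  # (N_loc,) |theta*| for the direction gate (0 for ds2)


def build_targets(
    batch: list[AnnotatedImage],
    anchors: AnchorSet,
    pos_thresh: float = 0.5,
    neg_thresh: float = 0.5,
    sampler_size: int = 256,
    sampler_pos_fraction: float = 0.25,
    rng: np.random.Generator | int | None = None,
) -> BatchTargets:
    """Match, sample and encode ground truth for every image in a batch."""
    rng = np.random.default_rng(rng)
    n_anchors = len(anchors)
    samp_idx, samp_lab = [], []
    pos_idx, box_t, ang_v, ccw, tags, gate = [], [], [], [], [], []
    for img_i, ann in enumerate(batch):
        offset = img_i * n_anchors
        match = match_anchors(anchors, ann.gt_boxes(), pos_thresh, neg_thresh)
        pos, neg = sample_minibatch(match, sampler_size, sampler_pos_fraction, rng)
        samp_idx.append(np.concatenate([pos, neg]) + offset)
        samp_lab.append(np.concatenate([np.ones(len(pos)), np.zeros(len(neg))]))
        if len(pos) == 0:
            continue
        gt_idx = match.gt_index[pos]
        gt_centers = corners_to_center(ann.gt_boxes()[gt_idx])
        box_t.append(encode_boxes(gt_centers, anchors.centers[pos]))
        pos_idx.append(pos + offset)
        for g in gt_idx:
            rec = ann.records[g]
            if ann.dataset_tag == "ds1":
                theta = rec.theta
                ang_v.append(abs(theta))
                ccw.append(1.0 if theta > 0 else 0.0)
                gate.append(abs(theta))
                tags.append("ds1")
            else:
                ang_v.append(0.0)
                ccw.append(0.0)
                gate.append(0.0)  # box-only anchors never enter the direction gate
                tags.append("ds2")
    empty = np.zeros(0)
    return BatchTargets(
        sampled_indices=np.concatenate(samp_idx).astype(np.int64),
        sampled_labels=np.concatenate(samp_lab).astype(np.float32),
        positive_indices=(
            np.concatenate(pos_idx).astype(np.int64) if pos_idx else empty.astype(np.int64)
        ),
        box_targets=np.concatenate(box_t) if box_t else np.zeros((0, 4)),
        angle_values=np.asarray(ang_v, dtype=np.float32),
        ccw_labels=np.asarray(ccw, dtype=np.float32),
        ds_tags=np.asarray(tags, dtype=object),
        gate_values=np.asarray(gate, dtype=np.float32),
    )


def training_loss(
    head: Tensor, targets: BatchTargets, weights: LossWeights = LossWeights()
) -> tuple[Tensor, LossBreakdown]:
    """The four-term objective on a (N, A, 9) head tensor for one batch."""
    flat = head.reshape(-1, head.shape[-1])
    sampled = flat[targets.sampled_indices]
    p_obj = sampled[:, OBJ_SLICE].softmax(axis=-1)[:, 1]
    l_obj = objectness_loss(p_obj, targets.sampled_labels, weights.gamma)
    if targets.positive_indices.size:
        positives = flat[targets.positive_indices]
        l_loc = localization_loss(positives[:, BOX_SLICE], targets.box_targets, weights.delta)
        v_pred = positives[:, ANGLE_COL].sigmoid()
        l_av = angle_value_loss(v_pred, targets.angle_values, targets.ds_tags, weights)
        p_ccw = positives[:, DIR_SLICE].softmax(axis=-1)[:, 1]
        l_ad = angle_direction_loss(
            p_ccw, targets.ccw_labels, targets.gate_values, weights.epsilon, weights.gamma
        )
    else:
        l_loc = Tensor(0.0)
        l_av = Tensor(0.0)
        l_ad = Tensor(0.0)
    return total_loss(l_loc, l_obj, l_av, l_ad, weights)


def _clip_global_norm(params, max_norm: float) -> None:
    total = math.sqrt(
        sum(float(np.sum(p.grad.astype(np.float64) ** 2)) for p in params if p.grad is not None)
    )
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= np.float32(scale)


def _batch_array(batch: list[AnnotatedImage]) -> np.ndarray:
    return np.stack([ann.image for ann in batch]).astype(np.float32)


def _save_training_state(
    path: str | Path, model: DetectionNetwork, opt: SGD, batcher: DualBatcher,
    sampler_rng: np.random.Generator, step: int,
) -> None:
    extra = {
        "step": step,
        "batcher": batcher.get_state(),
        "sampler_rng": sampler_rng.bit_generator.state,
        "velocity_count": len(opt._velocity),
    }
    arrays = {f"__velocity__{i}": v for i, v in enumerate(opt._velocity)}
    save_checkpoint(path, model, extra=extra, extra_arrays=arrays)


def train(
    cfg: TrainConfig,
    ds1: list[AnnotatedImage],
    ds2: list[AnnotatedImage] | None = None,
    log_path: str | Path | None = None,
    checkpoint_path: str | Path | None = None,
    resume_from: str | Path | None = None,
    progress: bool = False,
) -> tuple[DetectionNetwork, list[LossBreakdown]]:
    """Run the full training loop; returns the model and the per-step losses.

    ``ds2`` may be None, in which case the box-only stream aliases ``ds1``
    (every angle label is simply ignored on that side of the batch).
    ``resume_from`` restores a checkpoint written by this function — model
    weights, optimizer momentum and the data/sampler random streams — so the
    continued run reproduces the uninterrupted one exactly.
    """
    model = DetectionNetwork(cfg.network)
    model.set_training(True)
    anchors = cfg.network.make_anchors()
    batcher = DualBatcher(
        ds1, ds2, cfg.augmentation, input_size=cfg.network.input_size, seed=cfg.seed
    )
    sampler_rng = np.random.default_rng(cfg.seed + 1)
    opt = SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    start_step = 0
    if resume_from is not None:
        resumed, extra, extra_arrays = load_checkpoint(resume_from, with_arrays=True)
        if resumed.cfg != cfg.network:
            raise ValueError("resume checkpoint was trained with a different network config")
        model.load_state_arrays(resumed.state_arrays())
        model.set_training(True)
        for i in range(extra["velocity_count"]):
            opt._velocity[i][...] = extra_arrays[f"__velocity__{i}"]
        batcher.set_state(extra["batcher"])
        sampler_rng.bit_generator.state = extra["sampler_rng"]
        start_step = extra["step"]
    history: list[LossBreakdown] = []
    log_fh = open(log_path, "w") if log_path is not None else None
    if log_fh:
        log_fh.write(json.dumps({"config": _config_summary(cfg)}) + "\n")
    t0 = time.time()
    try:
        for step in range(start_step, cfg.total_steps):
            batch = batcher.next_batch()
            head = model(_batch_array(batch))
            targets = build_targets(
                batch,
                anchors,
                cfg.match_pos_thresh,
                cfg.match_neg_thresh,
                cfg.sampler_size,
                cfg.sampler_pos_fraction,
                sampler_rng,
            )
            loss, breakdown = training_loss(head, targets, cfg.loss)
            if not np.isfinite(breakdown.total):
                raise FloatingPointError(
                    f"non-finite loss at step {step}: {breakdown} "
                    f"(batch tags: {[b.dataset_tag for b in batch]})"
                )
            opt.zero_grad()
            loss.backward()
            if cfg.clip_grad_norm > 0:
                _clip_global_norm(opt.params, cfg.clip_grad_norm)
            opt.step(lr=cfg.lr_at(step))
            history.append(breakdown)
            if log_fh:
                log_fh.write(
                    json.dumps(
                        {
                            "step": step,
                            "loc": breakdown.loc,
                            "obj": breakdown.obj,
                            "av": breakdown.av,
                            "ad": breakdown.ad,
                            "total": breakdown.total,
                        }
                    )
                    + "\n"
                )
            if progress and (step % 50 == 0 or step == cfg.total_steps - 1):
                print(
                    f"step {step:5d}  total {breakdown.total:8.4f}  "
                    f"loc {breakdown.loc:.4f} obj {breakdown.obj:.4f} "
                    f"av {breakdown.av:.4f} ad {breakdown.ad:.4f}  "
                    f"({time.time() - t0:.0f}s)",
                    flush=True,
                )
            if (
                checkpoint_path is not None
                and cfg.checkpoint_every
                and (step + 1) % cfg.checkpoint_every == 0
            ):
                _save_training_state(checkpoint_path, model, opt, batcher, sampler_rng, step + 1)
    finally:
        if log_fh:
            log_fh.close()
    if checkpoint_path is not None:
        _save_training_state(checkpoint_path, model, opt, batcher, sampler_rng, cfg.total_steps)
    model.set_training(False)
    return model, history


def _config_summary(cfg: TrainConfig) -> dict:
    return asdict(cfg)


def detect_images(
    model: DetectionNetwork,
    images: list[np.ndarray],
    score_thresh: float = 0.5,
    nms_iou: float = 0.5,
    max_dets: int = 100,
    batch_size: int = 8,
) -> list[list[Detection]]:
    """Eval-mode forward + post-processing over a list of (H, W, C) images."""
    model.set_training(False)
    out: list[list[Detection]] = []
    anchors_cache: dict[tuple[int, int], object] = {}
    for start in range(0, len(images), batch_size):
        chunk = images[start : start + batch_size]
        shapes = {im.shape for im in chunk}
        if len(shapes) != 1:
            raise ValueError("images in one batch must share a shape")
        h, w = chunk[0].shape[:2]
        key = (w, h)
        if key not in anchors_cache:
            anchors_cache[key] = model.cfg.make_anchors(w, h)
        anchors = anchors_cache[key]
        head = model(np.stack(chunk).astype(np.float32)).data
        for i in range(len(chunk)):
            decoded = decode_head(head[i])
            out.append(postprocess(decoded, anchors, score_thresh, nms_iou, max_dets))
    return out
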