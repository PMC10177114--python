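"""The detector's four-term training objective.

    L = lambda_loc * L_loc + lambda_obj * L_obj + lambda_av * L_av + lambda_ad * L_ad

* ``L_loc`` — Huber penalty on box-encoding residuals, averaged over the
  N_loc sampled positive anchors.
* ``L_obj`` — focal loss on objectness over all N_obj sampled anchors, with
  pt = 1 - |p - p*|.
* ``L_av`` — squared error on the absolute angle value over positives, with
  dataset-dependent weights: angle-labeled images (ds1) pull toward the true
  value, box-only images (ds2) pull toward zero; the ds2 weight is 0 by
  default so box-only data contributes nothing to this term.
* ``L_ad`` — focal loss on the rotation direction, over the gated set of
  positives whose true absolute angle exceeds epsilon (nearly-unrotated faces
  have an ill-defined sign and are excluded).

All functions accept either :class:`~oriface.nn.Tensor` (differentiable, used
in training) or plain arrays/floats; empty reductions return 0 rather than
NaN so batches without positives are harmless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "huber",
    "focal",
    "localization_loss",
    "objectness_loss",
    "angle_value_loss",
    "angle_direction_loss",
    "total_loss",
]

PROB_FLOOR = 1e-7  # keeps log(pt) finite


@dataclass(frozen=True)
class LossWeights:
    lambda_loc: float = 1.0
    lambda_obj: float = 5.0
    lambda_av: float = 1.0
    lambda_ad: float = 10.0
    lambda_ds1: float = 10.0
    lambda_ds2: float = 0.0
    delta: float = 1.0  # Huber transition point
    gamma: float = 2.0  # focal focusing exponent
    epsilon: float = 0.025  # direction-loss gate on |theta*| (half-turns)

    def __post_init__(self):
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"loss weight {name} must be non-negative, got {v}")


@dataclass
class LossBreakdown:
    loc: float
    obj: float
    av: float
    ad: float
    total: float


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def huber(a, delta: float = 1.0):
    """Piecewise-quadratic penalty: 0.5 a^2 if |a| <= delta else delta|a| - 0.5 delta^2.

    Tensor input keeps the differentiable float32 path; plain arrays/floats
    are evaluated in float64.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if isinstance(a, Tensor):
        return a.huber(delta)
    a = np.asarray(a, dtype=np.float64)
    absa = np.abs(a)
    return np.where(absa <= delta, 0.5 * a * a, delta * absa - 0.5 * delta * delta)


def focal(pt, gamma: float = 2.0):
    """Focal loss FL(pt) = -(1 - pt)^gamma * log(pt); gamma = 0 is cross-entropy.

    Tensor input keeps the differentiable float32 path; plain arrays/floats
    are evaluated in float64.
    """
    if isinstance(pt, Tensor):
        pt_t = pt.clip_min(PROB_FLOOR)
        return (1.0 - pt_t).pow(gamma) * -(pt_t.log())
    pt = np.maximum(np.asarray(pt, dtype=np.float64), PROB_FLOOR)
    return -((1.0 - pt) ** gamma) * np.log(pt)


def localization_loss(pred_encodings, target_encodings, delta: float = 1.0):
    """Mean over sampled positives of the coordinate-summed Huber residual."""
    pred = _wrap(pred_encodings)
    targ = np.asarray(
        target_encodings.data if isinstance(target_encodings, Tensor) else target_encodings,
        dtype=np.float32,
    )
    if pred.shape != targ.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {targ.shape}")
    n = pred.shape[0] if pred.data.ndim else 0
    if n == 0:
        return Tensor(0.0) if isinstance(pred_encodings, Tensor) else 0.0
    out = huber(pred - Tensor(targ), delta).sum() * (1.0 / n)
    return out if isinstance(pred_encodings, Tensor) else float(out.data)


def _focal_on_match(p, labels, gamma):
    """Mean FL(1 - |p - p*|) for binary labels; pt is linear in p."""
    p_t = _wrap(p)
    lab = np.asarray(labels, dtype=np.float32)
    pt = p_t * lab + (1.0 - p_t) * (1.0 - lab)
    return focal(pt, gamma).mean()


def objectness_loss(p, labels, gamma: float = 2.0):
    """Mean focal loss over the sampled anchors; labels are {0,1} objectness."""
    p_arr = p.data if isinstance(p, Tensor) else np.asarray(p)
    if p_arr.size == 0:
        return Tensor(0.0) if isinstance(p, Tensor) else 0.0
    out = _focal_on_match(p, labels, gamma)
    return out if isinstance(p, Tensor) else float(out.data)


def angle_value_loss(
    pred_values,
    true_values,
    ds_tags,
    weights: LossWeights = LossWeights(),
):
    """Dataset-masked squared error on the absolute angle value.

    ``ds_tags`` holds "ds1"/"ds2" per positive anchor; normalization is by the
    total positive count N_loc regardless of tag mix, so re-tagging images
    changes the loss exactly through the ds1/ds2 weighting.
    """
    pred = _wrap(pred_values)
    tags = np.asarray(ds_tags)
    bad = set(tags.tolist()) - {"ds1", "ds2"}
    if bad:
        raise ValueError(f"unknown dataset tags: {sorted(bad)}")
    n_loc = pred.shape[0] if pred.data.ndim else 0
    if n_loc == 0:
        return Tensor(0.0) if isinstance(pred_values, Tensor) else 0.0
    true = np.asarray(
        true_values.data if isinstance(true_values, Tensor) else true_values, dtype=np.float32
    )
    is_ds1 = (tags == "ds1").astype(np.float32)
    # ds1: 0.5 (v* - v)^2; ds2: 0.5 v^2 (pull toward zero)
    target = true * is_ds1
    w = weights.lambda_ds1 * is_ds1 + weights.lambda_ds2 * (1.0 - is_ds1)
    diff = pred - Tensor(target)
    out = (Tensor(w) * diff * diff * 0.5).sum() * (1.0 / n_loc)
    return out if isinstance(pred_values, Tensor) else float(out.data)


def angle_direction_loss(
    p_ccw,
    ccw_labels,
    true_values,
    epsilon: float = 0.025,
    gamma: float = 2.0,
):
    """Focal direction loss over the gate I = {i : true |theta*_i| > epsilon}.

    ``true_values`` are ground-truth absolute angles per anchor; anchors from
    box-only images must be passed with value 0 so the gate drops them.
    Returns 0 when the gate is empty.
    """
    p_t = _wrap(p_ccw)
    true = np.asarray(
        true_values.data if isinstance(true_values, Tensor) else true_values, dtype=np.float32
    )
    gate = np.flatnonzero(true > epsilon)
    if gate.size == 0:
        return Tensor(0.0) if isinstance(p_ccw, Tensor) else 0.0
    lab = np.asarray(ccw_labels, dtype=np.float32)[gate]
    out = _focal_on_match(p_t[gate], lab, gamma)
    return out if isinstance(p_ccw, Tensor) else float(out.data)


def total_loss(loc, obj, av, ad, weights: LossWeights = LossWeights()):
    """Weighted sum of the four terms; returns (total, LossBreakdown)."""
    parts = [loc, obj, av, ad]
    tensors = [_wrap(p) for p in parts]
    vals = [float(t.data) for t in tensors]
    if any(not np.isfinite(v) for v in vals):
        raise FloatingPointError(f"non-finite loss component: {vals}")
    total = (
        tensors[0] * weights.lambda_loc
        + tensors[1] * weights.lambda_obj
        + tensors[2] * weights.lambda_av
        + tensors[3] * weights.lambda_ad
    )
    breakdown = LossBreakdown(vals[0], vals[1], vals[2], vals[3], float(total.data))
    return total, breakdown
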