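"""Anchor grids, ground-truth matching and the box regression coding.

The detector scores a fixed set of prior boxes (anchors) tied to feature-map
cells at four scales.  At the reference 400x400 input the grid holds
exactly 20,058 anchors; training marks anchors positive/negative by IoU and
regresses box offsets in the anchor-relative (tx, ty, tw, th) coding.
"""

import numpy as np

from oriface import (
    corners_to_center,
    decode_boxes,
    encode_boxes,
    generate_anchors,
    match_anchors,
    sample_minibatch,
)
from oriface.synth import SyntheticSceneSpec, generate_scene

anchors = generate_anchors(400, 400)
print(f"400x400 input -> {len(anchors)} anchors over grids "
      f"{[f'{w}x{h}' for w, h in anchors.grid_sizes]} (6 per cell)")

# match a synthetic scene's ground truth at the benchmark scale
scene = generate_scene(SyntheticSceneSpec(size=128), rng=0)
anchors128 = generate_anchors(128, 128)
match = match_anchors(anchors128, scene.gt_boxes())
pos = match.positive_indices
print(f"\n128x128 scene with {len(scene.records)} face(s): "
      f"{len(anchors128)} anchors, {len(pos)} positive")

pos_idx, neg_idx = sample_minibatch(match, size=64, pos_fraction=0.25, rng=0)
print(f"sampled mini-batch: {len(pos_idx)} positives + {len(neg_idx)} negatives "
      f"(imbalance control for the focal objectness loss)")

# encode/decode round trip for the first positive anchor
gt = corners_to_center(scene.gt_boxes()[match.gt_index[pos[0]]])
enc = encode_boxes(gt, anchors128.centers[pos[0]])
dec = decode_boxes(enc, anchors128.centers[pos[0]])
print(f"\nencoding of gt {np.round(gt, 1)} against its anchor: {np.round(enc, 3)}")
print(f"decoding restores the box exactly: {np.round(dec, 1)}")
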