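"""Train a tiny detector on synthetic scenes and use it end to end.

A deliberately short run (a few hundred steps on a handful of scenes) that
shows the full loop: dual-dataset batching, the four-term loss, detection
and face normalization.  Expect partial convergence only — the scaled
benchmark in scripts/acceptance.py runs the full 2,000-step version.
"""

import numpy as np

from oriface import (
    AugmentationConfig,
    NetworkConfig,
    OpProbabilities,
    SyntheticSceneSpec,
    TrainConfig,
    detect_images,
    generate_dataset,
    normalize_face,
    train,
)

spec = SyntheticSceneSpec(size=128, channels=1)
scenes = generate_dataset(60, spec, seed=0)

probs = OpProbabilities(rot90ccw=0.5, hflip=0.5, vflip=0.5, tile2x2=0.0)
cfg = TrainConfig(
    network=NetworkConfig(input_channels=1, input_size=128, base_width=8, seed=0),
    augmentation=AugmentationConfig(ds1=probs, ds2=probs, t1=3, t2=1),
    total_steps=300,
    learning_rate=0.012,
    seed=0,
)
print(f"training {cfg.total_steps} steps on {len(scenes)} scenes "
      f"(batch {cfg.augmentation.t1}+{cfg.augmentation.t2})...")
model, history = train(cfg, scenes)
print(f"loss: {history[0].total:.2f} (step 0) -> {history[-1].total:.2f} (final); "
      f"components loc/obj/av/ad = "
      f"{history[-1].loc:.3f}/{history[-1].obj:.3f}/{history[-1].av:.3f}/{history[-1].ad:.3f}")

test_scene = generate_dataset(1, spec, seed=999)[0]
dets = detect_images(model, [test_scene.image], score_thresh=0.5)[0]
print(f"\nheld-out scene: {len(test_scene.records)} true face(s), "
      f"{len(dets)} detection(s)")
for d in dets[:3]:
    print(f"  box {np.round(d.box, 1)}  score {d.score:.2f}  "
          f"theta {d.theta:+.3f} ({d.theta * 180:+.1f} deg)")

if dets:
    chip = normalize_face(test_scene.image, dets[0], out_size=64).chip
    print(f"\nnormalized first face to a {chip.shape[0]}x{chip.shape[1]} chip "
          f"(rotated by {-dets[0].theta * 180:+.1f} deg, cropped, scaled); "
          f"chip intensity range [{chip.min():.2f}, {chip.max():.2f}]")
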