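"""Generate synthetic oriented-face scenes with exact ground truth.

Each scene holds elliptical face glyphs with two eye dots; the generator
records every glyph's bounding box, rotation angle and eye keypoints, so the
detector can be trained and scored with no external data.
"""

import numpy as np

from oriface import SyntheticSceneSpec, angle_from_keypoints, generate_dataset

spec = SyntheticSceneSpec(size=128, channels=1)
scenes = generate_dataset(5, spec, seed=42)

for i, scene in enumerate(scenes):
    print(f"scene {i}: {scene.image.shape[0]}x{scene.image.shape[1]} px, "
          f"{len(scene.records)} face(s)")
    for rec in scene.records:
        x0, y0, x1, y1 = rec.box
        recomputed = angle_from_keypoints(rec.keypoints)
        print(f"  box ({x0:5.1f},{y0:5.1f})-({x1:5.1f},{y1:5.1f})  "
              f"theta {rec.theta:+.3f} ({rec.theta * 180:+6.1f} deg)  "
              f"theta from eyes {recomputed:+.3f}")

thetas = [r.theta for s in scenes for r in s.records]
print(f"\n{len(thetas)} faces; angles span [{min(thetas):+.2f}, {max(thetas):+.2f}] "
      f"(drawn uniformly from (-1, 1])")
print("the recomputed angles match the sampled ones exactly: the generator is "
      "its own oracle")
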