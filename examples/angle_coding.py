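"""Rotation-angle coding: keypoints to angle, the value/sign split, and the
augmentation transforms.

Angles live in half-turns on (-1, 1]: multiply by 180 for degrees, positive
is counterclockwise.  The value/sign split is what lets a detector regress
nearly-upside-down faces without chasing the +-180 degree jump.
"""

from oriface import (
    KeypointPair,
    angle_distance,
    angle_from_keypoints,
    combine_angle,
    split_angle,
    transform_angle,
)

# A face whose left eye is at (30, 60) and right eye at (50, 40): the eye
# line climbs to the right, so the face is rotated counterclockwise.
kp = KeypointPair(xl=30, yl=60, xr=50, yr=40)
theta = angle_from_keypoints(kp)
print(f"eye line {kp} -> theta = {theta:+.3f} half-turns = {theta * 180:+.1f} degrees")

s = split_angle(theta)
print(f"split: absolute value {s.value:.3f}, counterclockwise={s.ccw}; "
      f"recombined -> {combine_angle(s):+.3f}")

# The same face under the three training augmentations:
for op in ("rot90ccw", "hflip", "vflip"):
    print(f"after {op:8s}: theta' = {transform_angle(theta, op):+.3f}")

# Wraparound distance: nearly-180-degree rotations coded +0.99 and -0.99 are
# geometrically 3.6 degrees apart, not 356.4.
d = angle_distance(0.99, -0.99)
print(f"distance(+0.99, -0.99) = {d:.3f} half-turns = {d * 180:.1f} degrees")
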