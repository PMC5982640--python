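"""Extract the canonical kinematic feature vector from a skeletal trial.

Features live in the body-anchored personal coordinate system, so they are
identical wherever the subject stands and whichever way they face.
"""

import numpy as np

from rehabmotion import SyntheticMotionSpec, simulate_abduction
from rehabmotion.features import assessment_preset, extract_features

seq, _ = simulate_abduction(SyntheticMotionSpec(seed=7))
features = extract_features(seq, assessment_preset())

print(f"{len(features)} frames, {len(features.feature_names)} channels, "
      f"speeds valid from frame {features.valid_from} (15-frame buffer)")
for name in features.feature_names:
    col = features.column(name)[features.valid_from:]
    print(f"  {name:28s} min {np.min(col):8.3f}  max {np.max(col):8.3f}")
# hip_right_frontal_angle peaks near the commanded 40 deg of abduction;
# the shoulder-center channels show the small counter-sway of the trunk
# (two bumps of a few cm/s), and pelvis_lr_speed stays near zero because
# this execution has no pelvis drift.
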