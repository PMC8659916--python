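"""Build a training dataset: rotation augmentation, patching, splitting.

Demonstrates the bookkeeping used at full camera scale (1920 x 1200 frames
-> 28 patches each; 30 recorded frames augmented to 65; an 11-frame holdout
giving a 1512 / 308 split) on cheap constant frames, then builds real
synthetic pairs at desk scale.
"""

import numpy as np

from holophase.dataset import (
    PairedFrame,
    augment_rotations,
    make_patches,
    split_frames,
    synthetic_patch_pairs,
)

frames = [
    PairedFrame(hologram=np.broadcast_to(np.float64(i), (1920, 1200)),
                phase=np.broadcast_to(np.float64(i), (1920, 1200)),
                frame_id=f"f{i:02d}")
    for i in range(30)
]
augmented = augment_rotations(frames, target_count=65, seed=1)
manifest = split_frames(augmented, validation_frames=11, seed=1)
print(f"patches per 1920x1200 frame: {len(make_patches(frames[0]))}")
print(f"frames after 90/180-degree augmentation: {len(augmented)}")
print(f"train / validation patch pairs: {len(manifest.train)} / {len(manifest.validation)}")

holos, phases = synthetic_patch_pairs(8, seed=3)
print(f"synthetic pairs: holograms {holos.shape} in "
      f"[{holos.min():.2f}, {holos.max():.2f}], phases {phases.shape} in "
      f"[{phases.min():.2f}, {phases.max():.2f}]")

# Both arrays are normalized to [-1, 1] — the value range the tanh-headed
# generator trains against; the split is frame-disjoint so no patch of a
# validation frame ever appears in training.
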