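"""Expand a segmented dataset four-fold with seeded, auditable transforms.

Each original keeps company with factor-1 variants (random flip,
rotation, shift, zoom); every variant records its parent and draw seed,
so it can be regenerated bit-exactly — augmentation as a reproducible
accounting operation, not a one-way randomization.
"""

import numpy as np

from larvadet import (
    AugmentationPolicy,
    augment_dataset,
    augment_image,
    generate_dataset,
    segment_dataset,
)

captures = generate_dataset(5, 0, "chironomid", seed=1, image_side=700)
samples, _ = segment_dataset(captures, quality_threshold=50.0)

policy = AugmentationPolicy(factor=4, seed=99)
augmented = augment_dataset(samples, policy)
print(f"{len(samples)} originals -> {len(augmented)} samples (factor {policy.factor})")

variant = next(s for s in augmented if s.parent_id is not None)
print(f"variant {variant.sample_id}: parent {variant.parent_id}, "
      f"draw_seed {variant.draw_seed}, transform {variant.transform}")

parent = next(s for s in samples if s.sample_id == variant.parent_id)
redo = augment_image(parent, policy, variant.draw_seed)
print("regenerated from lineage, bit-identical:",
      bool(np.array_equal(redo.grid, variant.grid)))
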