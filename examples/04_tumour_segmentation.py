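"""Seeded tumour segmentation with Hoshen-Kopelman cleanup.

Selects the brightest voxel of a chosen subtraction-DCE slice as the seed,
grows the enhancing region, labels the connected components with the
Hoshen-Kopelman union-find scan, and keeps the largest one.
"""

import numpy as np

from breastmwi import (
    GrowthCriterion,
    default_lower_bound,
    generate_phantom,
    grow_tumour,
    hoshen_kopelman,
    largest_component,
    malignant_preset,
    median_filter3,
    select_seed,
)
from breastmwi.pipeline import body_mask_otsu

ph = generate_phantom(malignant_preset(seed=1))

# the tumour is >1 cm, so the salt-and-pepper noise is median filtered away
sub = median_filter3(ph.sub_dce)

seed = select_seed(sub, ph.tumour_slice)
print(f"automatic seed at {seed.index}, intensity {seed.intensity:.1f} "
      f"(slice {seed.slice_index})")

body = body_mask_otsu(ph.dixon_i)
lower = default_lower_bound(sub, body)
print(f"automatic lower intensity bound (mean - 3 sigma of body, floored): {lower:.2f}")

grown = grow_tumour(sub, seed, GrowthCriterion(lower))
components = hoshen_kopelman(grown)
tumour = largest_component(components)
print(f"region growing: {int(grown.data.sum())} voxels in "
      f"{int(components.max())} component(s); largest kept: {int(tumour.sum())} voxels")

truth = ph.truth.data == -3
inter = (tumour & truth).sum()
print(f"tumour Dice vs truth: {2*inter/(tumour.sum()+truth.sum()):.3f} "
      "(spiculated malignant shape)")
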