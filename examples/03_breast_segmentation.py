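"""Step through the breast-region segmentation on a phantom.

Runs the stage operations one by one — sternum location, fat region
growing, union-mask construction, symmetry evaluation, boundary extraction,
skin refinement — and scores each against the phantom's ground truth.
"""

import numpy as np

from breastmwi import (
    benign_preset,
    build_breast_mask,
    correct_bias_field,
    extract_boundaries,
    generate_phantom,
    grow_fat_mask,
    locate_sternum,
    mask_symmetry_mse,
    minmax_normalise,
    pick_fat_seed,
    refine_skin,
)
from breastmwi.pipeline import body_mask_otsu

ph = generate_phantom(benign_preset(seed=1))

# preprocessing: one shared coil field estimated on the fat-only volume
bias = correct_bias_field(ph.dixon_f, mask=body_mask_otsu(ph.dixon_f), n_classes=1)
dixon_f = minmax_normalise(bias.corrected)
dixon_w = minmax_normalise(ph.dixon_w.with_data(ph.dixon_w.data / bias.field.data))

sternum = locate_sternum(dixon_w)
print(f"sternum plane at coronal index {sternum.coronal_index} "
      f"(truth {ph.sternum_truth.coronal_index})")

seed = pick_fat_seed(dixon_f, sternum)
fat = grow_fat_mask(dixon_f, seed)
print(f"fat region grown from seed {seed}: {int(fat.data.sum())} voxels")

mask = build_breast_mask(fat, dixon_w, sternum)
ev = mask_symmetry_mse(mask)
print(f"breast mask: {int(mask.data.sum())} voxels, sagittal asymmetry "
      f"{ev.mse_percent:.1f}% (invasive={ev.invasive}; >10% would flag invasion)")

skin0, chest = extract_boundaries(mask, sternum)
skin = refine_skin(skin0, dixon_w, fat)
print(f"skin contour: {int(skin.data.sum())} voxels, "
      f"chest-wall boundary: {int(chest.data.sum())} voxels")

truth_skin = ph.truth.data == -2
inter = (skin.data.astype(bool) & truth_skin).sum()
print(f"skin Dice vs truth: {2*inter/(skin.data.sum()+truth_skin.sum()):.3f}")
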