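"""Tumour segmentation on subtraction DCE volumes.

Seed selection, 3D region growing with an automatic lower intensity bound,
Hoshen-Kopelman connected-component labelling (raster-scan union-find, the
percolation-theory formulation), largest-component isolation, and a manual
correction hook for vessel removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ValidationError
from .volumes import LabelMap, ScalarVolume, binary_labelmap

logger = logging.getLogger(__name__)

# raster-order (lexicographically negative) neighbour offsets
_OFFSETS_6 = [(-1, 0, 0), (0, -1, 0), (0, 0, -1)]
_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) < (0, 0, 0)
]


@dataclass
class TumourSeed:
    """Seed voxel for tumour region growing."""

    index: tuple[int, int, int]
    intensity: float
    slice_index: int
    manual: bool = False


@dataclass
class GrowthCriterion:
    """Intensity window of the growing region.

    ``lower_intensity_bound`` (L) is the minimum intensity a tumour voxel can
    take; the growing window is seed +/- t with t = seed intensity - L.
    """

    lower_intensity_bound: float


def select_seed(
    sub_dce: ScalarVolume,
    slice_index: int,
    manual_index: tuple[int, int, int] | None = None,
) -> TumourSeed:
    """Pick the seed voxel on one transverse slice of the subtraction volume.

    Automatic mode takes the brightest voxel of the slice (the tumour usually
    enhances most; ties resolved to the smallest linear index); a manual
    index overrides it when the brightest voxel is not tumour.
    """
    data = np.asarray(sub_dce.data, dtype=float)
    if manual_index is not None:
        idx = tuple(int(v) for v in manual_index)
        if any(i < 0 or i >= s for i, s in zip(idx, data.shape)):
            raise IndexError(f"manual index {idx} outside volume {data.shape}")
        return TumourSeed(
            index=idx, intensity=float(data[idx]), slice_index=int(idx[2]), manual=True
        )
    if not 0 <= slice_index < data.shape[2]:
        raise IndexError(f"slice {slice_index} outside volume of {data.shape[2]} slices")
    plane = data[:, :, slice_index]
    i, j = np.unravel_index(np.argmax(plane), plane.shape)
    idx = (int(i), int(j), int(slice_index))
    return TumourSeed(
        index=idx, intensity=float(data[idx]), slice_index=int(slice_index), manual=False
    )


def default_lower_bound(
    sub_dce: ScalarVolume, body_mask: LabelMap, floor: float = 1.0
) -> float:
    """Automatic lower intensity bound: mean - 3 std of all body voxels.

    On subtraction images the statistic can go non-positive, so the bound is
    clamped to a small positive floor (default 1 on the 0-255 scale). Fully
    overridable via configuration.
    """
    body = body_mask.binary()
    if not body.any():
        raise DegenerateInputError("empty body mask")
    vals = np.asarray(sub_dce.data, dtype=float)[body]
    return float(max(floor, vals.mean() - 3.0 * vals.std()))


def grow_tumour(
    sub_dce: ScalarVolume,
    seed: TumourSeed,
    criterion: GrowthCriterion,
    connectivity: int = 6,
) -> LabelMap:
    """3D region growing from the seed within the intensity window.

    The window is [L, seed + t] with t = seed intensity - L; since the seed
    is the slice maximum the upper bound is usually vacuous. The result is
    the connected component of in-window voxels containing the seed.
    """
    lo = float(criterion.lower_intensity_bound)
    if lo > seed.intensity:
        raise ValidationError(
            f"lower bound {lo} exceeds the seed intensity {seed.intensity}"
        )
    data = np.asarray(sub_dce.data, dtype=float)
    t = seed.intensity - lo
    hi = seed.intensity + t
    window = (data >= lo) & (data <= hi)
    if connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 26:
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValidationError(f"connectivity must be 6 or 26, got {connectivity}")
    labels, _ = ndimage.label(window, structure=structure)
    return binary_labelmap(labels == labels[seed.index], sub_dce)


def hoshen_kopelman(mask: LabelMap | np.ndarray, connectivity: int = 6) -> np.ndarray:
    """Hoshen-Kopelman cluster labelling of a binary volume.

    Single raster scan with union-find: each occupied site takes the root
    label of its already-visited neighbours (merging their clusters) or opens
    a new cluster. Labels are finally made contiguous 1..K in
    first-occurrence order. Returns an int32 array of component labels
    (0 = background).
    """
    data = mask.binary() if isinstance(mask, LabelMap) else np.asarray(mask)
    vals = set(np.unique(data).tolist())
    if not vals <= {0, 1, True, False}:
        raise ValidationError("hoshen_kopelman expects a binary volume")
    occ = data.astype(bool)
    if connectivity == 6:
        offsets = _OFFSETS_6
    elif connectivity == 26:
        offsets = _OFFSETS_26
    else:
        raise ValidationError(f"connectivity must be 6 or 26, got {connectivity}")

    labels = np.zeros(occ.shape, dtype=np.int32)
    parent: list[int] = [0]  # parent[i] of provisional label i; 0 unused

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return root

    nx, ny, nz = occ.shape
    next_label = 1
    for x, y, z in zip(*np.nonzero(occ)):
        roots = set()
        for dx, dy, dz in offsets:
            px, py, pz = x + dx, y + dy, z + dz
            if 0 <= px < nx and 0 <= py < ny and 0 <= pz < nz and labels[px, py, pz]:
                roots.add(find(labels[px, py, pz]))
        if not roots:
            parent.append(next_label)
            labels[x, y, z] = next_label
            next_label += 1
        else:
            target = min(roots)
            labels[x, y, z] = target
            for r in roots:
                parent[r] = target

    # resolve to roots and relabel contiguously in first-occurrence order
    remap: dict[int, int] = {}
    out = np.zeros_like(labels)
    for x, y, z in zip(*np.nonzero(occ)):
        root = find(labels[x, y, z])
        if root not in remap:
            remap[root] = len(remap) + 1
        out[x, y, z] = remap[root]
    return out


def largest_component(labelled: np.ndarray) -> np.ndarray:
    """Binary mask of the largest component of a labelled volume (ties: smallest label)."""
    labelled = np.asarray(labelled)
    if labelled.max() < 1:
        raise DegenerateInputError("no components in the labelled volume")
    sizes = np.bincount(labelled.ravel())
    sizes[0] = -1
    best = int(np.argmax(sizes))  # argmax returns the first (smallest) label on ties
    return labelled == best


def apply_manual_correction(
    mask: LabelMap,
    keep_roi: LabelMap | np.ndarray | tuple | None = None,
    remove_roi: LabelMap | np.ndarray | tuple | None = None,
) -> LabelMap:
    """Manual clean-up of a tumour mask (e.g. removing an attached vessel).

    ``remove_roi`` voxels are cleared; if ``keep_roi`` is given the mask is
    intersected with it. ROIs may be binary masks on the same grid or index
    boxes ``((x0, x1), (y0, y1), (z0, z1))`` with exclusive upper bounds.
    The operation is logged for provenance.
    """
    m = mask.binary().copy()

    def to_mask(roi) -> np.ndarray:
        if roi is None:
            return None
        if isinstance(roi, LabelMap):
            mask.require_same_grid(roi, "mask and ROI")
            return roi.binary()
        if isinstance(roi, np.ndarray):
            if roi.shape != m.shape:
                raise ValidationError("ROI array must match the mask shape")
            return roi.astype(bool)
        box = np.zeros_like(m)
        (x0, x1), (y0, y1), (z0, z1) = roi
        box[x0:x1, y0:y1, z0:z1] = True
        return box

    keep = to_mask(keep_roi)
    remove = to_mask(remove_roi)
    if keep is None and remove is None:
        logger.warning("manual correction called with no ROI: no-op")
        return binary_labelmap(m, mask)
    if remove is not None:
        m &= ~remove
        logger.info("manual correction removed %d voxels", int(remove.sum()))
    if keep is not None:
        m &= keep
        logger.info("manual correction kept %d candidate voxels", int(keep.sum()))
    return binary_labelmap(m, mask)
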