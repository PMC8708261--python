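"""Breast-region segmentation from Dixon fat-only / water-only volumes.

The stage builds a binary mask of the breast region (skin + fat +
fibroglandular tissue), detects invasive-tumour asymmetry via a sagittal
mirror comparison, and separates skin, chest-wall boundary, fat and
fibroglandular tissue into a signed label map.

Axis convention (see :mod:`breastmwi.volumes`): axis 0 left->right,
axis 1 posterior->anterior, axis 2 inferior->superior. "Coronal index"
means an index along axis 1; the sagittal mirror flips axis 0; a
transverse (axial) slice fixes axis 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .errors import DegenerateInputError, SeedError, SternumNotFoundError, ValidationError
from .volumes import LabelMap, ScalarVolume, binary_labelmap, DEFAULT_LEGEND


@dataclass
class SternumLocation:
    """Anterior-most coronal plane of the sternum and the left-right midline."""

    coronal_index: int
    midline_index: int


@dataclass
class MaskEvaluation:
    """Sagittal-symmetry evaluation of a breast mask.

    ``mse_percent`` is the mean squared difference between the mask and its
    sagittal mirror, scaled by 100; values above ``threshold`` flag an
    invasive tumour (one breaching the pectoral boundary).
    """

    mse_percent: float
    invasive: bool
    threshold: float = 10.0


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValidationError(f"connectivity must be 6 or 26, got {connectivity}")


def ball(radius: int) -> np.ndarray:
    """Euclidean ball structuring element in voxel units."""
    r = int(radius)
    grid = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (grid**2).sum(axis=0) <= r * r


def _largest_component(mask: np.ndarray, structure: np.ndarray) -> np.ndarray:
    """Largest connected component; ties broken by smallest minimum linear index."""
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        flat = labels.ravel()
        first = {lab: np.flatnonzero(flat == lab)[0] for lab in best}
        best = [min(best, key=lambda lab: first[lab])]
    return labels == best[0]


# ---------------------------------------------------------------------------
# Step 1: sternum location + fat region growing + watershed split
# ---------------------------------------------------------------------------

def locate_sternum(dixon_w: ScalarVolume) -> SternumLocation:
    """Locate the anterior-most coronal plane of the sternum.

    Scans the left-right midline column from outside the body towards the
    spine (anterior to posterior) and returns the first coronal plane holding
    a voxel brighter than the mean intensity of the water-only volume.
    """
    data = np.asarray(dixon_w.data, dtype=float)
    mid = data.shape[0] // 2
    mean = data.mean()
    column = data[mid, :, :]  # (y, z)
    counts = (column > mean).sum(axis=1)
    hits = np.flatnonzero(counts > 0)
    if hits.size == 0:
        raise SternumNotFoundError(
            "no voxel above the mean intensity along the midline column"
        )
    return SternumLocation(coronal_index=int(hits.max()), midline_index=mid)


def pick_fat_seed(dixon_f: ScalarVolume, sternum: SternumLocation) -> tuple[int, int, int]:
    """Pick a fat-region seed anterior to the sternum plane.

    The brightest fat-only voxel anterior of the sternum lies inside breast
    fat (organs and muscle are dark in the fat-only sequence), making it a
    robust automatic seed for the fat region growing.
    """
    data = np.asarray(dixon_f.data, dtype=float)
    anterior = data[:, sternum.coronal_index + 1 :, :]
    if anterior.size == 0:
        raise DegenerateInputError("no voxels anterior to the sternum plane")
    idx = np.unravel_index(np.argmax(anterior), anterior.shape)
    return (int(idx[0]), int(idx[1]) + sternum.coronal_index + 1, int(idx[2]))


def grow_fat_mask(
    dixon_f: ScalarVolume,
    seed: tuple[int, int, int],
    connectivity: int = 6,
) -> LabelMap:
    """Region growing of fat in the fat-only volume.

    The intensity window is automatic: lower limit = mean + one standard
    deviation of the volume, upper limit = the volume maximum. The result is
    the connected component of in-window voxels that contains the seed.
    """
    data = np.asarray(dixon_f.data, dtype=float)
    lo = data.mean() + data.std()
    hi = data.max()
    seed = tuple(int(v) for v in seed)
    seed_val = data[seed]
    if not (lo <= seed_val <= hi):
        raise SeedError(
            f"seed intensity {seed_val:.2f} outside the fat window [{lo:.2f}, {hi:.2f}]"
        )
    window = (data >= lo) & (data <= hi)
    labels, _ = ndimage.label(window, structure=_structure(connectivity))
    return binary_labelmap(labels == labels[seed], dixon_f)


def split_fat_watershed(fat_mask: LabelMap, connectivity: int = 6) -> LabelMap:
    """Separate breast fat from thoracic fat when the two are merged.

    When the mask already holds several connected components the anterior one
    (containing the anterior-most voxel) is returned unchanged. When breast
    and thoracic fat merged into a single component, a marker-based watershed
    on the distance transform splits the mask at its narrow neck; the basin
    reaching deepest posterior (thoracic fat sits behind the pectoral wall)
    is discarded and the component containing the anterior-most voxel is
    kept.
    """
    fore = fat_mask.binary()
    if not fore.any():
        raise DegenerateInputError("empty fat mask")
    structure = _structure(connectivity)

    def anterior_component(mask: np.ndarray) -> np.ndarray:
        labels, n = ndimage.label(mask, structure=structure)
        if n <= 1:
            return mask
        ys = np.where(mask)[1]
        # component containing the anterior-most voxel (ties: raster order)
        xs, ys_all, zs = np.where(mask)
        order = np.argsort(-ys_all, kind="stable")
        lab = labels[xs[order[0]], ys_all[order[0]], zs[order[0]]]
        return labels == lab

    labels, n = ndimage.label(fore, structure=structure)
    if n > 1:
        return binary_labelmap(anterior_component(fore), fat_mask)

    dist = ndimage.distance_transform_edt(fore)
    markers_mask = dist >= 0.5 * dist.max()
    markers, n_markers = ndimage.label(markers_mask, structure=structure)
    if n_markers < 2:
        return binary_labelmap(fore, fat_mask)
    basins = watershed(-dist, markers, mask=fore)

    xs, ys, zs = np.where(fore)
    post = np.argsort(ys, kind="stable")[0]  # posterior-most voxel, raster tie-break
    posterior_label = basins[xs[post], ys[post], zs[post]]
    kept = fore & (basins != posterior_label)
    if not kept.any():
        return binary_labelmap(fore, fat_mask)
    return binary_labelmap(anterior_component(kept), fat_mask)


# ---------------------------------------------------------------------------
# Step 2: breast mask
# ---------------------------------------------------------------------------

def build_breast_mask(
    fat_mask: LabelMap,
    dixon_w: ScalarVolume,
    sternum: SternumLocation,
    threshold_ratio: float = 0.25,
    dilation_radius: int = 3,
) -> LabelMap:
    """Union mask of skin + fat + fibroglandular tissue.

    The fat mask is dilated by a Euclidean ball (radius 3 voxels, roughly the
    reported areolar skin thickness at 1 mm voxels), everything anterior to
    the sternum plane inside the dilated mask's lateral/axial bounding box is
    whited out, the result is multiplied by the water-only volume and
    binarised at ``mean + threshold_ratio * std`` of the product, and finally
    OR-ed with the dilated mask.
    """
    fat_mask.require_same_grid(dixon_w, "fat mask and Dixon-W")
    fat = fat_mask.binary()
    if not fat.any():
        raise DegenerateInputError("empty fat mask")
    dilated = ndimage.binary_dilation(fat, structure=ball(dilation_radius))

    whiteout = dilated.copy()
    xs, _, zs = np.where(dilated)
    x0, x1 = xs.min(), xs.max()
    z0, z1 = zs.min(), zs.max()
    whiteout[x0 : x1 + 1, sternum.coronal_index + 1 :, z0 : z1 + 1] = True

    product = whiteout * np.asarray(dixon_w.data, dtype=float)
    threshold = product.mean() + threshold_ratio * product.std()
    binarised = product > threshold
    return binary_labelmap(binarised | dilated, fat_mask)


# ---------------------------------------------------------------------------
# Step 3 + 4: symmetry evaluation and invasive completion
# ---------------------------------------------------------------------------

def mask_symmetry_mse(mask: LabelMap, threshold: float = 10.0) -> MaskEvaluation:
    """Mean squared difference (x100) between a mask and its sagittal mirror.

    Computed over all voxels of the volume; a value above ``threshold``
    (default 10%) indicates an invasive tumour, whose asymmetric bite out of
    one breast cannot be mirrored.
    """
    a = mask.binary().astype(np.float64)
    b = a[::-1, :, :]
    mse = float(((a - b) ** 2).mean() * 100.0)
    return MaskEvaluation(mse_percent=mse, invasive=mse > threshold, threshold=threshold)


def complete_invasive_mask(mask: LabelMap, dixon_i: ScalarVolume) -> LabelMap:
    """Fill the pectoral-invasion hole of an asymmetric breast mask.

    The mask is united with its sagittal mirror; voxels present in only one
    of the two are kept only where the in-phase intensity reaches its volume
    mean, and remaining holes are closed morphologically.
    """
    mask.require_same_grid(dixon_i, "mask and Dixon-I")
    m = mask.binary()
    f = m[::-1, :, :]
    both = m & f
    only_one = (m | f) & ~both
    data = np.asarray(dixon_i.data, dtype=float)
    kept = both | (only_one & (data >= data.mean()))
    filled = ndimage.binary_fill_holes(kept)
    return binary_labelmap(filled, mask)


# ---------------------------------------------------------------------------
# Step 5 + 6: skin and chest-wall boundary
# ---------------------------------------------------------------------------

def _first_hit_scan(m: np.ndarray) -> np.ndarray:
    """First mask voxel along rays from the left, right and anterior borders.

    Operates on the full volume at once (equivalent to a per-transverse-slice
    scan): for each (y, z) line the first foreground voxel from x- and from
    x+, and for each (x, z) column the first foreground voxel from y+
    (anterior). Posterior rays are excluded so the back/chest wall is never
    claimed as skin.
    """
    first_left = m & (np.cumsum(m, axis=0) == 1)
    rev = m[::-1, :, :]
    first_right = (rev & (np.cumsum(rev, axis=0) == 1))[::-1, :, :]
    rev_y = m[:, ::-1, :]
    first_ant = (rev_y & (np.cumsum(rev_y, axis=1) == 1))[:, ::-1, :]
    return first_left | first_right | first_ant


def extract_boundaries(
    mask: LabelMap,
    sternum: SternumLocation,
    invasive: bool = False,
    original_mask: LabelMap | None = None,
    dilation_radius: int = 3,
    connectivity: int = 6,
) -> tuple[LabelMap, LabelMap]:
    """Split the breast-mask contour into skin and chest-wall boundary.

    The 1-voxel mask contour is scanned from the left, right and anterior
    borders to seed the skin contour; the remaining contour, restricted to
    planes at or behind the sternum, seeds the chest-wall boundary. After a
    largest-component cleanup both contours are thickened by a radius-3 ball
    and clipped by the mask. For invasive exams the region filled by the
    symmetric completion (final mask minus original mask) is added to the
    chest-wall boundary.

    Returns ``(skin, chestwall)``, disjoint binary masks contained in
    ``mask``.
    """
    m = mask.binary()
    if not m.any():
        raise DegenerateInputError("empty mask")
    structure = _structure(connectivity)
    # a 1-voxel curved surface is only connected diagonally, so the contour
    # component steps always use 26-connectivity
    surf_structure = _structure(26)

    eroded = ndimage.binary_erosion(m, structure=structure, border_value=0)
    contour = m & ~eroded

    skin0 = _first_hit_scan(m) & contour
    rest = contour & ~skin0
    rest[:, sternum.coronal_index + 1 :, :] = False  # black out anterior of the sternum
    chest0 = _largest_component(rest, surf_structure)

    skin1 = _largest_component(contour & ~chest0, surf_structure)
    chest1 = contour & ~skin1
    chest1[:, sternum.coronal_index + 1 :, :] = False  # boundary stays posterior

    b = ball(dilation_radius)
    skin = ndimage.binary_dilation(skin1, structure=b) & m
    chest = ndimage.binary_dilation(chest1, structure=b) & m

    if invasive:
        if original_mask is None:
            raise ValidationError("invasive extraction requires the original mask")
        diff = m & ~original_mask.binary()
        chest |= ndimage.binary_dilation(diff, structure=b) & m

    chest &= ~skin
    return binary_labelmap(skin, mask), binary_labelmap(chest, mask)


def refine_skin(
    skin: LabelMap,
    dixon_w: ScalarVolume,
    fat_mask: LabelMap,
    threshold_ratio: float = 0.25,
) -> LabelMap:
    """Trim the thick skin contour to the water-bright non-fat shell.

    Multiplying the water-only volume by the negated fat mask leaves skin and
    fibroglandular tissue; binarising (same mean + std/4 statistic as the
    breast-mask threshold) and intersecting with the dilated skin contour
    yields a skin layer of spatially varying thickness.
    """
    skin.require_same_grid(dixon_w, "skin and Dixon-W")
    img = np.asarray(dixon_w.data, dtype=float) * ~fat_mask.binary()
    threshold = img.mean() + threshold_ratio * img.std()
    refined = (img > threshold) & skin.binary()
    return binary_labelmap(refined, skin)


# ---------------------------------------------------------------------------
# Step 7: label map assembly
# ---------------------------------------------------------------------------

def assemble_labelmap(
    breast_mask: LabelMap,
    skin: LabelMap,
    chestwall: LabelMap,
    tumour: LabelMap | None = None,
) -> LabelMap:
    """Assemble the final signed label map.

    Precedence: tumour (-3) > skin (-2) > chest-wall boundary (-1) >
    foreground (1) > background (0). The foreground (fat + fibroglandular)
    is whatever remains of the breast mask after removing the other tissues.
    """
    m = breast_mask.binary()
    s = skin.binary()
    c = chestwall.binary()
    labels = np.zeros(m.shape, dtype=np.int8)
    labels[m] = 1
    labels[c] = -1
    labels[s] = -2
    if tumour is not None:
        t = tumour.binary()
        outside = t & ~m
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} tumour voxels lie outside the breast mask; "
                "labelling them -3 anyway",
                stacklevel=2,
            )
        labels[t] = -3
    return LabelMap(
        data=labels,
        spacing=breast_mask.spacing,
        origin=breast_mask.origin,
        orientation=breast_mask.orientation,
        legend=dict(DEFAULT_LEGEND),
    )
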