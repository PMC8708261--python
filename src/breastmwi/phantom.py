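"""Synthetic multi-sequence breast MRI phantom.

Generates co-registered Dixon fat-only (F), water-only (W), in-phase
(I = F + W) and subtraction DCE volumes on one grid, together with
ground-truth labels, so that every pipeline stage can be exercised and
scored without patient data.

Geometry: a chest slab (posterior) holding a thoracic cavity with organs and
thoracic fat behind a pectoral muscle wall; two hemiellipsoidal breasts on
the anterior chest surface, joined by a subcutaneous fat bridge across the
midline; a 2 mm skin shell over the whole body surface; a water-bright
sternum bar at the midline. Fat is bright in F; fibroglandular tissue, skin
and muscle are bright in W; tumours enhance only in the subtraction volume.
Malignant tumours are a core ellipsoid with radial spicules, optionally
crossing the pectoral boundary (invasive), in which case the tumour tissue
is dark in both Dixon channels and bites a hole out of the breast mask.

What the phantom does NOT emulate: MR acquisition physics, partial-volume
mixing, coil-dependent noise correlation, or any specific patient anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .breast_seg import SternumLocation
from .errors import GridMismatchError, ValidationError
from .volumes import DEFAULT_LEGEND, LabelMap, ScalarVolume, binary_labelmap


@dataclass
class TumourSpec:
    """Tumour geometry inside the right breast.

    ``kind``: none | benign (ellipsoid) | malignant (spiculated core).
    ``invasive`` malignant tumours cross the pectoral boundary and are dark
    in both Dixon channels, carving an asymmetric hole out of the breast
    mask.
    """

    kind: str = "none"
    semiaxes_mm: tuple[float, float, float] = (7.0, 6.0, 5.5)
    core_radius_mm: float = 5.0
    spicule_count: int = 8
    spicule_length_mm: float = 6.0
    invasive: bool = False


@dataclass
class PhantomSpec:
    """Geometry, contrast-regime and degradation parameters of the phantom."""

    shape: tuple[int, int, int] = (52, 42, 34)
    spacing: tuple[float, float, float] = (0.99, 0.99, 1.0)
    breast_semiaxes_mm: tuple[float, float, float] = (11.0, 22.0, 12.0)
    skin_thickness_mm: float = 2.0
    fibro_blob_count: int = 4
    fibro_blob_radius_mm: float = 7.0
    tumour: TumourSpec = field(default_factory=TumourSpec)
    #: True emulates a fat-predominant exam whose fibroglandular mode sits
    #: close to fat in the in-phase histogram (engages the alternative
    #: breakpoint table); False gives the well-separated bimodal regime.
    overlap_regime: bool = False
    #: bore a fat channel through the pectoral wall so breast and thoracic
    #: fat merge into one component (exercises the watershed split)
    merged_fat: bool = False
    bias_amplitude: float = 0.2
    bias_order: int = 2
    salt_pepper_density: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.salt_pepper_density <= 0.2:
            raise ValidationError("salt-and-pepper density must lie in [0, 0.2]")
        if not 0.0 <= self.bias_amplitude <= 0.5:
            raise ValidationError("bias amplitude must lie in [0, 0.5]")
        if self.tumour.kind not in ("none", "benign", "malignant"):
            raise ValidationError(f"unknown tumour kind '{self.tumour.kind}'")


@dataclass
class PhantomSet:
    """The four synthetic sequences plus every ground truth the tests need."""

    dixon_f: ScalarVolume
    dixon_w: ScalarVolume
    dixon_i: ScalarVolume
    sub_dce: ScalarVolume
    truth: LabelMap
    true_bias: ScalarVolume
    sternum_truth: SternumLocation
    body: LabelMap
    vessel: LabelMap | None = None
    tumour_slice: int | None = None
    tumour_extent_mm: float | None = None
    spec: PhantomSpec | None = None


def benign_preset(seed: int = 0) -> PhantomSpec:
    """Well-separated histogram, 12 mm benign ellipsoid tumour."""
    return PhantomSpec(tumour=TumourSpec(kind="benign"), seed=seed)


def malignant_preset(seed: int = 0) -> PhantomSpec:
    """Fat-predominant histogram, spiculated malignant tumour, non-invasive."""
    return PhantomSpec(
        tumour=TumourSpec(kind="malignant", core_radius_mm=5.0),
        overlap_regime=True,
        seed=seed,
    )


def invasive_preset(seed: int = 0) -> PhantomSpec:
    """Large malignant tumour breaching the pectoral boundary.

    The tumour consumes a large share of one breast (mirroring the reported
    invasive case, which extended about 8 cm), so the breast mask loses more
    than 10% of the volume's voxels relative to its sagittal mirror.
    """
    return PhantomSpec(
        tumour=TumourSpec(
            kind="malignant",
            core_radius_mm=11.0,
            semiaxes_mm=(15.0, 20.0, 14.5),
            spicule_count=10,
            spicule_length_mm=7.0,
            invasive=True,
        ),
        overlap_regime=True,
        seed=seed,
    )


def _ellipsoid(shape, centre, semiaxes_vox) -> np.ndarray:
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, centre, semiaxes_vox):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _spiculated(shape, centre, core_vox, count, length_vox, rng) -> np.ndarray:
    """Core ellipsoid plus radial cosine-tapered spicules."""
    mask = _ellipsoid(shape, centre, core_vox)
    idx = np.indices(shape).astype(float)
    rel = idx - np.asarray(centre, dtype=float).reshape(3, 1, 1, 1)
    core_r = float(np.mean(core_vox))
    for _ in range(count):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        proj = (rel * d.reshape(3, 1, 1, 1)).sum(axis=0)
        radial = np.sqrt(np.maximum((rel**2).sum(axis=0) - proj**2, 0.0))
        along = proj - core_r * 0.6  # spicules start near the core surface
        frac = np.clip(along / max(length_vox, 1e-6), 0.0, 1.0)
        width = 2.2 * np.cos(frac * np.pi / 2.0) + 0.5
        mask |= (along >= 0) & (along <= length_vox) & (radial <= width)
    return mask


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomSet:
    """Deterministically build the four sequences, truths, and degradations."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    sp = np.asarray(spec.spacing, dtype=float)
    nx, ny, nz = shape

    def vox(mm, axis):
        return float(mm) / sp[axis]

    breast_ax = tuple(vox(a, i) for i, a in enumerate(spec.breast_semiaxes_mm))
    chest_top = 15
    mid = nx // 2

    # --- geometry -----------------------------------------------------
    chest = np.zeros(shape, dtype=bool)
    chest[2 : nx - 2, 2 : chest_top + 1, 2 : nz - 2] = True
    cavity = np.zeros(shape, dtype=bool)
    cavity[4 : nx - 4, 4:11, 4 : nz - 4] = True
    cavity &= chest

    z_mid = nz // 2
    cx_l, cx_r = int(round(nx * 0.25)), int(round(nx * 0.75))
    breast_l = _ellipsoid(shape, (cx_l, chest_top, z_mid), breast_ax)
    breast_r = _ellipsoid(shape, (cx_r, chest_top, z_mid), breast_ax)
    ys = np.arange(ny).reshape(1, -1, 1)
    anterior_half = ys >= chest_top
    breasts = (breast_l | breast_r) & anterior_half

    body = chest | breasts
    dist_in = ndimage.distance_transform_edt(body, sampling=sp)
    skin = body & (dist_in <= spec.skin_thickness_mm)
    interior = body & ~skin

    # retromammary fat: a subcutaneous layer between the pectoral muscle and
    # the breasts, connecting the fat of the two breasts across the midline
    footprint_fat2d = breasts.any(axis=1)
    footprint_fat2d = ndimage.binary_dilation(footprint_fat2d, iterations=3)
    # stepped ledge: the layer narrows as it rises so the mask's chest
    # bottom slopes inward and the boundary contour stays directly above it
    retro_fat = np.zeros(shape, dtype=bool)
    base2d = breasts.any(axis=1)
    for step, row in enumerate(range(chest_top, chest_top - 3, -1)):
        ring = ndimage.binary_dilation(base2d, iterations=1 + step)
        retro_fat[:, row, :] |= ring
    retro_fat &= chest & ~skin & ~cavity

    sternum = np.zeros(shape, dtype=bool)
    sternum[mid - 2 : mid + 2, 8 : 11, 8 : nz - 8] = True
    sternum &= chest & ~skin

    thoracic_fat = _ellipsoid(
        shape, (mid, 6, z_mid), (vox(14, 0), vox(3.0, 1), vox(9, 2))
    ) & cavity
    organs = cavity & ~thoracic_fat  # merged channel carved out below
    muscle = chest & ~cavity & ~skin & ~sternum & ~retro_fat

    anterior_interior = interior & breasts & anterior_half

    # fibroglandular blobs behind each breast centre + a wedge to the nipple
    fibro = np.zeros(shape, dtype=bool)
    r_fib = tuple(vox(spec.fibro_blob_radius_mm, i) for i in range(3))
    if spec.overlap_regime:
        blob_count, blob_scale = 1, 0.75
    else:
        blob_count, blob_scale = spec.fibro_blob_count, 1.0
    hotspot_region = _ellipsoid(shape, (cx_l, chest_top + 1, z_mid), (3.0, 3.0, 3.0))
    for cx in (cx_l, cx_r):
        base = np.asarray([cx, chest_top + breast_ax[1] * 0.36, z_mid], dtype=float)
        for _ in range(blob_count):
            jitter = rng.normal(scale=1.0, size=3) * np.array([2.0, 1.5, 2.0])
            shape_factors = (0.74, 1.45, 0.74)  # prolate: deep, not wide
            fibro |= _ellipsoid(
                shape, base + jitter,
                tuple(a * f * blob_scale for a, f in zip(r_fib, shape_factors)),
            )
        # wedge: a thin fibroglandular duct reaching the skin at the nipple
        xs_g, ys_g, zs_g = np.ogrid[:nx, :ny, :nz]
        axis_r = np.sqrt((xs_g - cx) ** 2 + (zs_g - z_mid) ** 2)
        fibro |= (axis_r <= 1.8) & (ys_g >= chest_top + breast_ax[1] * 0.55) & np.ones(shape, bool)
    fibro &= anterior_interior & (ys >= chest_top + 2) & ~hotspot_region

    # --- tumour --------------------------------------------------------
    t = spec.tumour
    tumour = np.zeros(shape, dtype=bool)
    vessel = np.zeros(shape, dtype=bool)
    tumour_slice = None
    tumour_extent_mm = None
    if t.kind != "none":
        if t.kind == "benign":
            ax_vox = tuple(vox(a, i) for i, a in enumerate(t.semiaxes_mm))
            if any(2 * a >= 2 * b for a, b in zip(ax_vox, breast_ax)):
                raise ValidationError("tumour does not fit inside the breast")
            centre = (cx_r, chest_top + breast_ax[1] * 0.45, z_mid)
            tumour = _ellipsoid(shape, centre, ax_vox)
            tumour_extent_mm = 2.0 * max(t.semiaxes_mm)
        else:
            core = tuple(vox(t.core_radius_mm, i) for i in range(3))
            if t.invasive:
                core = tuple(vox(a, i) for i, a in enumerate(t.semiaxes_mm))
                centre = (cx_r, chest_top + 9, z_mid)
            else:
                if 2 * t.core_radius_mm + 2 * t.spicule_length_mm >= 2 * min(
                    spec.breast_semiaxes_mm
                ) * 2:
                    raise ValidationError("tumour does not fit inside the breast")
                centre = (cx_r, chest_top + breast_ax[1] * 0.4, z_mid)
            tumour = _spiculated(
                shape,
                centre,
                core,
                t.spicule_count,
                vox(t.spicule_length_mm, 1),
                rng,
            )
            if not t.invasive:
                tumour &= breasts  # keep a non-invasive tumour inside the breast
            else:
                tumour &= body
            extent = 2 * max(core) + 2 * vox(t.spicule_length_mm, 1)
            tumour_extent_mm = float(extent * sp.mean())
            # a thin blood vessel touching the tumour (requires manual cleanup)
            xs_g, ys_g, zs_g = np.ogrid[:nx, :ny, :nz]
            vr = np.sqrt((ys_g - centre[1]) ** 2 + (zs_g - (z_mid + 2)) ** 2)
            vessel = (
                (vr <= 1.2)
                & (xs_g >= centre[0] - 14)
                & (xs_g <= centre[0] - int(round(np.mean(core))) + 2)
                & body
            )
        tumour &= body
        tumour_slice = z_mid

    fat = anterior_interior & ~fibro & ~tumour

    merged_channel = np.zeros(shape, dtype=bool)
    if spec.merged_fat:
        merged_channel[cx_l + 7 : cx_l + 8, 6 : chest_top - 1, z_mid : z_mid + 1] = True
        merged_channel &= chest & ~skin
        muscle &= ~merged_channel

    # --- ground truth ---------------------------------------------------
    # Skin truth: the shell over the breast region (breast surfaces and the
    # inter-breast chest front), not the back/lateral body skin the breast
    # model never covers. Chest-wall truth: the ~3 mm tissue band straddling
    # the breast-base plane under the breast footprint (predominantly
    # muscle, but the boundary layer includes nearby tissue).
    truth = np.zeros(shape, dtype=np.int8)
    label1 = fat | fibro
    footprint2d = (label1 | tumour).any(axis=1)  # (x, z) columns
    footprint_tight = np.broadcast_to(footprint2d[:, None, :], shape)
    footprint_wide = np.broadcast_to(
        ndimage.binary_dilation(footprint2d, iterations=3)[:, None, :], shape
    )
    # stepped like the retromammary ledge: directly under the breast in the
    # upper rows, wider where the boundary meets the pectoral sheet
    band = (
        (ys >= chest_top - 2) & (ys <= chest_top - 1) & footprint_tight
    ) | ((ys >= chest_top - 4) & (ys <= chest_top - 3) & footprint_wide)
    truth[(body & ~skin) & band] = -1
    near_breast = (
        ndimage.distance_transform_edt(~(anterior_interior | retro_fat), sampling=sp)
        <= 3.0
    )
    truth[skin & near_breast] = -2
    truth[label1 & ~band] = 1
    # subcutaneous ledge fat beyond the boundary band is plain foreground fat
    truth[retro_fat & ~band & (truth == 0)] = 1
    truth[tumour] = -3

    # --- intensities ----------------------------------------------------
    def noisy(mask, mean, sigma, out):
        n = int(mask.sum())
        if n:
            out[mask] = mean + rng.normal(scale=sigma, size=n)

    F = np.abs(rng.normal(scale=2.0, size=shape))
    W = np.abs(rng.normal(scale=2.0, size=shape))
    fat_like = fat | retro_fat | merged_channel | thoracic_fat
    fg_w = 165.0 if spec.overlap_regime else 150.0
    noisy(fat_like, 200.0, 5.0, F)
    # a pure-adipose hotspot in the left breast pins the image maximum to
    # foreground fat, anchoring the upper end of the intensity-property map
    hotspot = _ellipsoid(shape, (cx_l, chest_top + 1, z_mid), (2.5, 2.5, 2.5)) & fat
    noisy(hotspot, 232.0, 1.0, F)
    noisy(fibro, 8.0, 3.0, F)
    noisy(skin, 10.0, 3.0, F)
    noisy(muscle, 10.0, 3.0, F)
    noisy(sternum, 12.0, 3.0, F)
    organs &= ~merged_channel
    noisy(organs, 12.0, 4.0, F)
    noisy(fat_like, 6.0, 3.0, W)
    noisy(fibro, fg_w, 8.0, W)
    noisy(skin, 150.0, 8.0, W)
    noisy(muscle, 120.0, 6.0, W)
    noisy(sternum, 170.0, 5.0, W)
    noisy(organs, 40.0, 6.0, W)
    if t.kind != "none":
        if t.invasive:
            noisy(tumour, 60.0, 5.0, F)
            noisy(tumour, 30.0, 5.0, W)
        else:
            noisy(tumour, 8.0, 3.0, F)
            noisy(tumour, fg_w, 8.0, W)
    F = np.clip(F, 0.0, None)
    W = np.clip(W, 0.0, None)
    I = F + W

    S = np.abs(rng.normal(scale=0.35, size=shape))
    if t.kind != "none":
        noisy(tumour, 190.0 if t.kind == "benign" else 200.0, 8.0, S)
        if vessel.any():
            noisy(vessel, 120.0, 10.0, S)
    S = np.clip(S, 0.0, None)

    # --- degradation ----------------------------------------------------
    def as_vol(arr):
        return ScalarVolume(arr, spacing=tuple(sp), origin=(0.0, 0.0, 0.0))

    bias_seed = int(rng.integers(0, 2**31 - 1))
    f_vol, bias = add_bias_field(as_vol(F), spec.bias_amplitude, spec.bias_order, bias_seed)
    field_arr = bias.data
    w_vol = as_vol(W * field_arr)
    i_vol = as_vol(I * field_arr)
    s_vol = as_vol(S * field_arr)
    sp_seed = int(rng.integers(0, 2**31 - 1))
    s_vol = add_salt_pepper(s_vol, spec.salt_pepper_density, sp_seed)

    truth_map = LabelMap(
        truth, spacing=tuple(sp), origin=(0.0, 0.0, 0.0), legend=dict(DEFAULT_LEGEND)
    )
    sternum_loc = SternumLocation(coronal_index=chest_top, midline_index=mid)
    return PhantomSet(
        dixon_f=f_vol,
        dixon_w=w_vol,
        dixon_i=i_vol,
        sub_dce=s_vol,
        truth=truth_map,
        true_bias=bias,
        sternum_truth=sternum_loc,
        body=binary_labelmap(body, truth_map),
        vessel=binary_labelmap(vessel, truth_map) if vessel.any() else None,
        tumour_slice=tumour_slice,
        tumour_extent_mm=tumour_extent_mm,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Degradations
# ---------------------------------------------------------------------------

def add_bias_field(
    vol: ScalarVolume, amplitude: float, order: int = 2, seed: int = 0
) -> tuple[ScalarVolume, ScalarVolume]:
    """Multiply the volume by a smooth random polynomial field.

    The field is a degree-``order`` polynomial in normalised coordinates,
    shifted and scaled so it has mean exactly 1 and range inside
    [1 - amplitude, 1 + amplitude]. Returns (degraded volume, true field).
    """
    if not 0.0 <= amplitude <= 0.5:
        raise ValidationError("bias amplitude must lie in [0, 0.5]")
    if amplitude == 0.0:
        return vol.with_data(vol.data.copy()), vol.with_data(np.ones(vol.shape))
    rng = np.random.default_rng(seed)
    coords = [np.linspace(-1.0, 1.0, n) for n in vol.shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    p = np.zeros(vol.shape, dtype=float)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                if i == j == k == 0:
                    continue
                p += rng.normal() * X**i * Y**j * Z**k
    p -= p.mean()
    s = np.abs(p).max()
    field = np.ones(vol.shape) if s == 0 else 1.0 + amplitude * p / s
    return vol.with_data(vol.data * field), vol.with_data(field)


def add_salt_pepper(vol: ScalarVolume, density: float, seed: int = 0) -> ScalarVolume:
    """Corrupt exactly round(density * N) voxels to 0 or the volume maximum.

    Half of the corrupted voxels go to 0 (pepper) and half to the pre-noise
    maximum (salt); a voxel already at its assigned value is flipped to the
    other extreme so every chosen voxel actually changes.
    """
    if not 0.0 <= density <= 0.2:
        raise ValidationError("salt-and-pepper density must lie in [0, 0.2]")
    data = np.asarray(vol.data, dtype=float).copy()
    n_total = data.size
    n_corrupt = int(round(density * n_total))
    if n_corrupt == 0:
        return vol.with_data(data)
    rng = np.random.default_rng(seed)
    positions = rng.choice(n_total, size=n_corrupt, replace=False)
    vmax = float(data.max())
    flat = data.ravel()
    half = n_corrupt // 2
    targets = np.full(n_corrupt, vmax)
    targets[:half] = 0.0
    for pos, target in zip(positions, targets):
        if flat[pos] == target:
            target = vmax if target == 0.0 else 0.0
        flat[pos] = target
    return vol.with_data(flat.reshape(vol.shape))


def dice(a: LabelMap, b: LabelMap, label: int) -> float:
    """Dice overlap of one label between two maps (1.0 when both sets are empty)."""
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing, atol=1e-6):
        raise GridMismatchError("label maps must share one grid")
    set_a = a.data == label
    set_b = b.data == label
    denom = int(set_a.sum()) + int(set_b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((set_a & set_b).sum()) / denom
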