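"""Pre-processing pipeline: registration, bias-field correction, Min-Max
normalisation and conditional 3x3x3 median filtering.

The stage order follows the clinical pipeline: the subtraction DCE volume is
registered onto the Dixon grid first, every sequence is then bias-corrected,
scaled to [0, 255], and (for tumours of at least 1 cm) median filtered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import DegenerateInputError, RegistrationError, ValidationError
from .volumes import (
    AffineTransform,
    LabelMap,
    ScalarVolume,
    _from_sitk,
    _to_sitk,
    resample_to_grid,
)


@dataclass
class NormalisationParams:
    """Target range of the Min-Max rescaling (defaults 0..255)."""

    newmin: float = 0.0
    newmax: float = 255.0

    def __post_init__(self):
        if not self.newmax > self.newmin:
            raise ValidationError("newmax must exceed newmin")


@dataclass
class BiasFieldResult:
    """Smooth multiplicative bias field and the corrected volume.

    Invariant: ``corrected * field`` reconstructs the input, and the field
    averages to 1 over the estimation mask.
    """

    corrected: ScalarVolume
    field: ScalarVolume


def _physical_bounds(vol: ScalarVolume) -> tuple[np.ndarray, np.ndarray]:
    lo = np.asarray(vol.origin)
    hi = lo + (np.asarray(vol.shape) - 1) * np.asarray(vol.spacing)
    return lo, hi


def register_linear(
    moving: ScalarVolume,
    fixed: ScalarVolume,
    metric: str = "mean_squares",
) -> tuple[AffineTransform, ScalarVolume]:
    """Affine registration of ``moving`` onto ``fixed`` with linear interpolation.

    Same-modality inputs use a mean-squared intensity difference metric;
    ``metric="mutual_information"`` is available for cross-sequence inputs.
    Returns the optimised transform (fixed physical space -> moving physical
    space) and the moving volume resampled onto the fixed grid.
    """
    if float(np.ptp(moving.data)) == 0 or float(np.ptp(fixed.data)) == 0:
        raise DegenerateInputError("cannot register constant volumes")
    lo_m, hi_m = _physical_bounds(moving)
    lo_f, hi_f = _physical_bounds(fixed)
    if np.any(hi_m < lo_f) or np.any(hi_f < lo_m):
        raise RegistrationError("fields of view do not overlap", metric_value=None)

    fixed_img = sitk.Cast(_to_sitk(fixed), sitk.sitkFloat32)
    moving_img = sitk.Cast(_to_sitk(moving), sitk.sitkFloat32)

    initial = sitk.CenteredTransformInitializer(
        fixed_img,
        moving_img,
        sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg = sitk.ImageRegistrationMethod()
    if metric == "mutual_information":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    else:
        reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(0.25, seed=12345)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=300,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-7,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=False)
    try:
        final = reg.Execute(fixed_img, moving_img)
    except RuntimeError as exc:  # pragma: no cover - ITK internal failures
        raise RegistrationError(f"registration failed: {exc}") from exc

    if hasattr(final, "Downcast"):
        final = final.Downcast()
    if isinstance(final, sitk.CompositeTransform):
        final = final.GetNthTransform(final.GetNumberOfTransforms() - 1)
        if hasattr(final, "Downcast"):
            final = final.Downcast()
    affine = sitk.AffineTransform(final)
    matrix = np.asarray(affine.GetMatrix(), dtype=float).reshape(3, 3)
    translation = np.asarray(affine.GetTranslation(), dtype=float)
    centre = np.asarray(affine.GetCenter(), dtype=float)
    # fold the rotation centre into the translation: T(x) = M (x - c) + c + t
    offset = translation + centre - matrix @ centre
    transform = AffineTransform(matrix, offset)
    resampled = resample_to_grid(moving, transform, fixed, interpolation="linear")
    return transform, resampled


def _poly_basis(shape, order: int) -> np.ndarray:
    """Monomial basis x^i y^j z^k (i+j+k <= order) on [-1, 1]^3 coordinates."""
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append((X**i * Y**j * Z**k).ravel())
    return np.stack(cols, axis=1)


def _fit_log_poly_field(
    data: np.ndarray,
    mask: np.ndarray,
    order: int,
    n_classes: int,
    n_iter: int,
) -> np.ndarray:
    """Alternating tissue-class / polynomial-surface fit of log intensities.

    Models log(I) = log(tissue class mean) + log(field) with a
    piecewise-constant tissue term and a degree-``order`` polynomial field;
    alternates class assignment and least-squares surface fitting.
    """
    fit_mask = mask & (data > 0)
    if fit_mask.sum() < 100:
        raise DegenerateInputError("too few positive voxels to estimate a bias field")
    basis = _poly_basis(data.shape, order)
    A = basis[fit_mask.ravel()]
    L = np.log(data[fit_mask])

    # class means initialised at quantiles of the log intensities
    means = np.quantile(L, np.linspace(0.1, 0.9, n_classes))
    log_field_vals = np.zeros_like(L)
    coeffs = np.zeros(A.shape[1])
    for _ in range(n_iter):
        resid_tissue = L - log_field_vals
        assign = np.argmin(np.abs(resid_tissue[:, None] - means[None, :]), axis=1)
        for c in range(n_classes):
            sel = assign == c
            if sel.any():
                means[c] = resid_tissue[sel].mean()
        target = L - means[assign]
        # bisquare-reweighted fit: voxels far off any class level (stray
        # tissue, hotspots) should not bend the surface
        w = np.ones_like(target)
        for _ in range(3):
            coeffs, *_ = np.linalg.lstsq(A * w[:, None], target * w, rcond=None)
            r = target - A @ coeffs
            mad = np.median(np.abs(r - np.median(r))) * 1.4826 + 1e-12
            u = np.abs(r) / (4.0 * mad)
            w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
        log_field_vals = A @ coeffs
    log_field = (basis @ coeffs).reshape(data.shape)
    return log_field


def correct_bias_field(
    vol: ScalarVolume,
    mask: LabelMap | None = None,
    method: str = "polyfit",
    order: int = 2,
    n_classes: int = 3,
    n_iter: int = 20,
    shrink_factor: int = 4,
    max_iterations: tuple[int, ...] = (50, 50, 30),
) -> BiasFieldResult:
    """Estimate and remove a smooth multiplicative intensity bias field.

    The default estimator alternates a piecewise-constant tissue model with
    a low-order polynomial surface fit in the log domain; ``method="n4"``
    switches to the SimpleITK N4 implementation. Either way the field is
    rescaled so its mean over ``mask`` (or the whole volume) is exactly 1
    and the corrected volume is the input divided by the field.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    if np.any(data < 0):
        raise ValidationError("bias-field correction expects a non-negative volume")
    if float(data.max()) == 0.0:
        raise DegenerateInputError("all-zero volume has no bias field to estimate")
    mask_arr = mask.data.astype(bool) if mask is not None else np.ones_like(data, bool)
    if not mask_arr.any():
        raise DegenerateInputError("empty estimation mask")

    if method == "polyfit":
        log_field = _fit_log_poly_field(data, mask_arr, order, n_classes, n_iter)
        field = np.exp(log_field)
    elif method == "n4":
        img = sitk.Cast(_to_sitk(vol), sitk.sitkFloat32)
        if mask is not None:
            mask_img = sitk.Cast(_to_sitk(mask), sitk.sitkUInt8)
        else:
            mask_img = sitk.Image(img.GetSize(), sitk.sitkUInt8)
            mask_img.CopyInformation(img)
            mask_img += 1
        shrink = max(1, int(shrink_factor))
        corrector = sitk.N4BiasFieldCorrectionImageFilter()
        corrector.SetMaximumNumberOfIterations(list(max_iterations))
        corrector.Execute(
            sitk.Shrink(img, [shrink] * 3), sitk.Shrink(mask_img, [shrink] * 3)
        )
        log_field = corrector.GetLogBiasFieldAsImage(img)
        field = np.exp(_from_sitk(log_field, vol, data_cast=np.float64))
    else:
        raise ValidationError(f"unknown bias-correction method '{method}'")

    field /= field[mask_arr].mean()
    corrected = data / field
    return BiasFieldResult(
        corrected=vol.with_data(corrected), field=vol.with_data(field)
    )


def minmax_normalise(
    vol: ScalarVolume, params: NormalisationParams | None = None
) -> ScalarVolume:
    """Linear Min-Max rescaling of a volume onto [newmin, newmax].

    Each voxel v maps to ``(v - min) / (max - min) * (newmax - newmin) + newmin``
    using the volume's own extrema, so the output range is exactly the target
    range.
    """
    params = params or NormalisationParams()
    data = np.asarray(vol.data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise DegenerateInputError("constant volume cannot be Min-Max normalised")
    out = (data - lo) / (hi - lo) * (params.newmax - params.newmin) + params.newmin
    return vol.with_data(out)


def median_filter3(vol: ScalarVolume) -> ScalarVolume:
    """3x3x3 median filter with edge replication at the borders."""
    if any(s < 3 for s in vol.shape):
        raise ValidationError("median_filter3 needs at least 3 voxels per axis")
    return vol.with_data(ndimage.median_filter(vol.data, size=3, mode="nearest"))


def should_median_filter(tumour_extent_mm: float) -> bool:
    """The median filter is skipped for infra-centimetric tumours.

    Filtering distorts the size and shape of small tumours, so it is applied
    only when the tumour's largest extent reaches 1 cm (boundary inclusive).
    """
    if tumour_extent_mm < 0:
        raise ValidationError("tumour extent must be non-negative")
    return tumour_extent_mm >= 10.0
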