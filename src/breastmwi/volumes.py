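"""Volume and label-map data model, NIfTI round-tripping, and grid resampling.

The in-memory convention used throughout the package:

* arrays are indexed ``data[i, j, k]`` with axis 0 running left -> right,
  axis 1 posterior -> anterior, and axis 2 inferior -> superior
  (orientation code ``("R", "A", "S")``);
* voxel indexing is 0-based and world coordinates are
  ``origin + index * spacing`` (axis-aligned grids);
* label maps use the convention 0 background, 1 fat + fibroglandular
  foreground, -1 chest-wall boundary, -2 skin, -3 tumour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import (
    DimensionalityError,
    GridMismatchError,
    TransformError,
    ValidationError,
)

RAS = ("R", "A", "S")

#: label -> tissue name, following the convention of the segmentation pipeline
DEFAULT_LEGEND = {
    0: "background",
    1: "fat+fibroglandular",
    -1: "chest-wall boundary",
    -2: "skin",
    -3: "tumour",
}

_ALLOWED_LABELS = frozenset(DEFAULT_LEGEND)


@dataclass
class ScalarVolume:
    """A 3D scalar grid with voxel spacing (mm), origin (mm) and orientation."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[str, str, str] = RAS

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if any(s <= 0 for s in self.data.shape):
            raise ValidationError("every volume dimension must be positive")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(np.asarray(self.data, dtype=float))):
            raise ValidationError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "ScalarVolume | LabelMap") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, rtol=0, atol=1e-6
        )

    def require_same_grid(self, other: "ScalarVolume | LabelMap", what: str = "volumes"):
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} must share one grid: {self.shape}/{self.spacing} vs "
                f"{other.shape}/{other.spacing}"
            )

    def with_data(self, data: np.ndarray) -> "ScalarVolume":
        return replace(self, data=data)

    def world_affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (mm) affine for this axis-aligned grid."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class LabelMap:
    """Integer volume on a :class:`ScalarVolume` grid.

    Values are restricted to {0, 1, -1, -2, -3}; ``legend`` maps each label
    to a tissue name.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[str, str, str] = RAS
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D label map, got {self.data.ndim} dimensions"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = self.data.astype(np.int8)
            if not np.array_equal(as_int, self.data):
                raise ValidationError("label map values must be integers")
            self.data = as_int
        present = set(np.unique(self.data).tolist())
        if not present <= _ALLOWED_LABELS:
            raise ValidationError(
                f"label values must lie in {sorted(_ALLOWED_LABELS)}, got {sorted(present)}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other) -> bool:
        return ScalarVolume.same_grid(self, other)  # type: ignore[arg-type]

    def require_same_grid(self, other, what: str = "volumes"):
        ScalarVolume.require_same_grid(self, other, what)  # type: ignore[arg-type]

    def binary(self) -> np.ndarray:
        """Boolean foreground array; raises unless the map is 0/1-valued."""
        vals = set(np.unique(self.data).tolist())
        if not vals <= {0, 1}:
            raise ValidationError(f"expected a binary mask, found labels {sorted(vals)}")
        return self.data.astype(bool)


def binary_labelmap(mask: np.ndarray, like: ScalarVolume | LabelMap) -> LabelMap:
    """Wrap a boolean array as a 0/1 LabelMap on the grid of ``like``."""
    return LabelMap(
        data=np.asarray(mask, dtype=np.int8),
        spacing=like.spacing,
        origin=like.origin,
        orientation=like.orientation,
        legend={0: "background", 1: "foreground"},
    )


@dataclass
class AffineTransform:
    """A linear map plus translation in world (mm) coordinates.

    Follows the resampling convention: the transform maps points in the
    *reference* (fixed) image physical space to the *moving* image physical
    space.
    """

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise TransformError("affine matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def translation_only(cls, t) -> "AffineTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Returns the transform equivalent to applying ``other`` then ``self``."""
        return AffineTransform(
            self.matrix @ other.matrix, self.matrix @ other.translation + self.translation
        )


# ---------------------------------------------------------------------------
# NIfTI IO
# ---------------------------------------------------------------------------

def _is_labelmap_file(path: Path) -> bool:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        try:
            meta = json.loads(sidecar.read_text())
            return meta.get("kind") == "labelmap"
        except (json.JSONDecodeError, OSError):
            return False
    return False


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume(path) -> ScalarVolume | LabelMap:
    """Read a NIfTI volume; returns a LabelMap when the sidecar marks it as one."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"expected a 3D NIfTI, got {data.ndim}D from {path}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    affine = img.affine
    origin = tuple(float(v) for v in affine[:3, 3])
    orientation = nib.aff2axcodes(affine)
    if _is_labelmap_file(path):
        meta = json.loads(_sidecar_path(path).read_text())
        legend = {int(k): v for k, v in meta.get("legend", {}).items()}
        return LabelMap(
            data=data.astype(np.int8),
            spacing=zooms,
            origin=origin,
            orientation=orientation,
            legend=legend or dict(DEFAULT_LEGEND),
        )
    return ScalarVolume(
        data=data.astype(np.float64),
        spacing=zooms,
        origin=origin,
        orientation=orientation,
    )


def write_volume(vol: ScalarVolume | LabelMap, path, provenance: dict | None = None):
    """Write a volume or label map as NIfTI-1 plus a JSON sidecar.

    Label maps are stored with a signed 8-bit on-disk type so negative labels
    round-trip exactly. The sidecar records the label legend (for label maps)
    and optional provenance (pipeline stage, parameters).
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    is_label = isinstance(vol, LabelMap)
    if not is_label and not np.all(np.isfinite(vol.data)):
        raise ValidationError("refusing to write a volume containing NaN/inf")
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing)
    affine[:3, 3] = vol.origin
    if is_label:
        img = nib.Nifti1Image(vol.data.astype(np.int8), affine)
        img.header.set_data_dtype(np.int8)
    else:
        img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
        img.header.set_data_dtype(np.float32)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    meta: dict = {"kind": "labelmap" if is_label else "scalar"}
    if is_label:
        meta["legend"] = {str(k): v for k, v in vol.legend.items()}
    if provenance:
        meta["provenance"] = provenance
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _to_sitk(vol: ScalarVolume | LabelMap) -> sitk.Image:
    # SimpleITK array order is (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0))))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def _from_sitk(img: sitk.Image, like: ScalarVolume | LabelMap, data_cast=None) -> np.ndarray:
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    if data_cast is not None:
        arr = arr.astype(data_cast)
    return arr


def sitk_transform_from_affine(t: AffineTransform) -> sitk.AffineTransform:
    st = sitk.AffineTransform(3)
    st.SetMatrix(t.matrix.ravel().tolist())
    st.SetTranslation(t.translation.tolist())
    return st


def resample_to_grid(
    moving: ScalarVolume | LabelMap,
    transform: AffineTransform,
    reference: ScalarVolume | LabelMap,
    interpolation: str = "linear",
) -> ScalarVolume | LabelMap:
    """Resample ``moving`` onto the grid of ``reference``.

    ``transform`` maps reference physical points to moving physical points
    (the standard resampling convention). Out-of-domain voxels are set to 0.
    Label maps are always resampled with nearest-neighbour interpolation.
    """
    if isinstance(moving, LabelMap):
        interpolation = "nearest"
    if interpolation not in ("linear", "nearest"):
        raise ValidationError(f"unknown interpolation '{interpolation}'")
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    moving_img = _to_sitk(moving)
    ref_img = _to_sitk(reference)
    out = sitk.Resample(
        moving_img,
        ref_img,
        sitk_transform_from_affine(transform),
        interp,
        0.0,
        moving_img.GetPixelID(),
    )
    if isinstance(moving, LabelMap):
        arr = _from_sitk(out, reference, data_cast=np.int8)
        return LabelMap(
            data=arr,
            spacing=reference.spacing,
            origin=reference.origin,
            orientation=reference.orientation,
            legend=dict(moving.legend),
        )
    arr = _from_sitk(out, reference, data_cast=np.float64)
    return ScalarVolume(
        data=arr,
        spacing=reference.spacing,
        origin=reference.origin,
        orientation=reference.orientation,
    )
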