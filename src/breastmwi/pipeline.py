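"""End-to-end orchestration: sequences -> label map -> dielectric maps.

``run_pipeline`` chains the pre-processing, breast-region segmentation,
tumour segmentation and dielectric mapping stages, records a provenance log
sufficient to re-execute the identical run, and optionally writes every
output as NIfTI + JSON.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu

from . import breast_seg, dielectric, preprocess, tumour_seg
from .breast_seg import MaskEvaluation
from .dielectric import DielectricMap, GMMParams
from .errors import StageError, ValidationError
from .phantom import PhantomSet
from .volumes import LabelMap, ScalarVolume, binary_labelmap, read_volume, write_volume


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, JSON-serialisable, with the defaults
    of the published procedure (Eq-style thresholds, 10% asymmetry cutoff,
    6-neighbour connectivity, 3/6/9 GHz)."""

    mse_threshold: float = 10.0
    connectivity: int = 6
    threshold_ratio: float = 0.25  # the mean + std/4 binarisation statistic
    frequencies_ghz: tuple[float, ...] = (3.0, 6.0, 9.0)
    tumour_class: str = "none"  # none | benign | malignant
    tumour_slice: int | None = None
    manual_seed: tuple[int, int, int] | None = None
    lower_bound: float | None = None
    lower_bound_floor: float = 1.0
    tumour_extent_mm: float | None = None
    skip_median: bool = False
    remove_roi: tuple | None = None  # ((x0,x1),(y0,y1),(z0,z1)) exclusive
    gmm_seed: int = 0
    predominance_ratio: float = 0.3
    #: re-register the subtraction volume onto the Dixon grid. Off by
    #: default: registration is only well-posed when the moving volume
    #: shares anatomy with the fixed one, which a background-suppressed
    #: subtraction volume often does not; enable for cross-acquisition data.
    register: bool = False
    registration_metric: str = "mutual_information"
    #: the watershed fat split runs only when the fat mask leaks deeper than
    #: this behind the sternum plane (merged breast/thoracic fat)
    watershed_margin_mm: float = 8.0

    def __post_init__(self):
        for f_ghz in self.frequencies_ghz:
            if not 3.0 <= f_ghz <= 10.0:
                raise ValidationError(
                    f"frequency {f_ghz} GHz outside the 3-10 GHz validity band"
                )
        if self.tumour_class not in ("none", "benign", "malignant"):
            raise ValidationError(f"unknown tumour class '{self.tumour_class}'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("frequencies_ghz") is not None:
            d["frequencies_ghz"] = tuple(d["frequencies_ghz"])
        if d.get("manual_seed") is not None:
            d["manual_seed"] = tuple(d["manual_seed"])
        return cls(**d)


@dataclass
class PipelineResult:
    """Everything a run produces, plus the provenance log."""

    labels: LabelMap
    mask_eval: MaskEvaluation
    gmm: GMMParams | None
    maps: dict[float, DielectricMap]
    tumour: LabelMap | None
    log: list[dict] = field(default_factory=list)
    intermediates: dict = field(default_factory=dict)


def body_mask_otsu(dixon_i: ScalarVolume) -> LabelMap:
    """Body mask by Otsu thresholding of the in-phase volume (air is dark)."""
    thr = threshold_otsu(np.asarray(dixon_i.data, dtype=float))
    return binary_labelmap(dixon_i.data > thr, dixon_i)


def _load_inputs(inputs) -> dict:
    if isinstance(inputs, PhantomSet):
        return {
            "dixon_f": inputs.dixon_f,
            "dixon_w": inputs.dixon_w,
            "dixon_i": inputs.dixon_i,
            "sub_dce": inputs.sub_dce,
            "tumour_slice": inputs.tumour_slice,
            "tumour_extent_mm": inputs.tumour_extent_mm,
        }
    vols = {k: read_volume(v) if not isinstance(v, (ScalarVolume, LabelMap)) else v
            for k, v in inputs.items() if v is not None}
    vols.setdefault("tumour_slice", None)
    vols.setdefault("tumour_extent_mm", None)
    return vols


def run_pipeline(
    config: PipelineConfig,
    inputs,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute preprocess -> breast segmentation -> tumour segmentation ->
    dielectric mapping; deterministic given the configured seeds.

    ``inputs`` is a :class:`~breastmwi.phantom.PhantomSet` or a mapping with
    keys ``dixon_f``, ``dixon_w``, ``dixon_i`` and optionally ``sub_dce``
    (paths or volumes).
    """
    log: list[dict] = []
    inter: dict = {}

    def stage(name: str, params: dict, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise StageError(name, params, exc) from exc
        log.append({"stage": name, "params": params, "seconds": round(time.perf_counter() - t0, 3)})
        return result

    vols = stage("load", {}, lambda: _load_inputs(inputs))
    dixon_f, dixon_w, dixon_i = vols["dixon_f"], vols["dixon_w"], vols["dixon_i"]
    sub_dce = vols.get("sub_dce")

    if sub_dce is not None and config.register:
        def do_register():
            transform, resampled = preprocess.register_linear(
                sub_dce, dixon_i, metric=config.registration_metric
            )
            inter["registration_transform"] = transform
            return resampled

        sub_dce = stage("register", {"metric": config.registration_metric}, do_register)

    # One coil profile per exam: the field is estimated on the fat-only
    # volume (a single dominant tissue with huge contrast against the rest,
    # so the tissue/field decomposition is well posed) and removed from every
    # co-registered sequence.
    def estimate_field():
        fat_mask = body_mask_otsu(dixon_f)
        return preprocess.correct_bias_field(dixon_f, mask=fat_mask, n_classes=1)

    bias = stage("bias_field", {"method": "polyfit", "classes": 1}, estimate_field)
    inter["bias_field"] = bias.field
    field = np.asarray(bias.field.data, dtype=float)
    dixon_f = bias.corrected
    dixon_w = dixon_w.with_data(np.asarray(dixon_w.data, float) / field)
    dixon_i = dixon_i.with_data(np.asarray(dixon_i.data, float) / field)
    if sub_dce is not None:
        sub_dce = sub_dce.with_data(np.asarray(sub_dce.data, float) / field)

    def normalise(vol, name):
        out = preprocess.minmax_normalise(vol)
        log.append(
            {"stage": f"normalise_{name}", "params": {
                "min": float(np.min(vol.data)), "max": float(np.max(vol.data)),
                "new_range": [0.0, 255.0]}}
        )
        return out

    dixon_f = normalise(dixon_f, "f")
    dixon_w = normalise(dixon_w, "w")
    dixon_i = normalise(dixon_i, "i")
    if sub_dce is not None:
        sub_dce = normalise(sub_dce, "sub")

    extent = config.tumour_extent_mm
    if extent is None:
        extent = vols.get("tumour_extent_mm")
    apply_median = not config.skip_median and (
        extent is None or preprocess.should_median_filter(extent)
    )
    if sub_dce is not None and apply_median:
        sub_dce = stage(
            "median_sub", {"tumour_extent_mm": extent}, lambda: preprocess.median_filter3(sub_dce)
        )

    sternum = stage("sternum", {}, lambda: breast_seg.locate_sternum(dixon_w))
    fat_seed = breast_seg.pick_fat_seed(dixon_f, sternum)
    fat = stage(
        "grow_fat",
        {"seed": list(fat_seed), "connectivity": config.connectivity},
        lambda: breast_seg.grow_fat_mask(dixon_f, fat_seed, config.connectivity),
    )
    # split merged breast/thoracic fat only when the mask leaks behind the
    # sternum plane; a healthy fat mask stays anterior of it
    margin_vox = config.watershed_margin_mm / fat.spacing[1]
    fat_min_y = int(np.where(fat.data)[1].min())
    if fat_min_y < sternum.coronal_index - margin_vox:
        fat = stage(
            "watershed_split", {"margin_mm": config.watershed_margin_mm},
            lambda: breast_seg.split_fat_watershed(fat, config.connectivity),
        )
    inter["fat_mask"] = fat
    mask = stage(
        "breast_mask",
        {"threshold_ratio": config.threshold_ratio},
        lambda: breast_seg.build_breast_mask(fat, dixon_w, sternum, config.threshold_ratio),
    )
    inter["initial_mask"] = mask
    ev = stage(
        "symmetry",
        {"threshold": config.mse_threshold},
        lambda: breast_seg.mask_symmetry_mse(mask, config.mse_threshold),
    )
    log[-1]["mse_percent"] = ev.mse_percent
    log[-1]["invasive"] = ev.invasive
    if ev.invasive:
        final_mask = stage(
            "invasive_completion", {}, lambda: breast_seg.complete_invasive_mask(mask, dixon_i)
        )
    else:
        final_mask = mask

    # The radius-3 dilation behind the breast mask inevitably drags a thin
    # shell of air into it. Mask voxels dark in the in-phase volume (below
    # its mean, the same statistic the invasive completion uses) are air,
    # not tissue; trimming them before contour extraction lets the scan rays
    # land on real skin instead of the dilated rim.
    i_data = np.asarray(dixon_i.data, dtype=float)
    final_mask = binary_labelmap(
        final_mask.binary() & (i_data >= i_data.mean()), final_mask
    )

    skin0, chest = stage(
        "boundaries",
        {"invasive": ev.invasive},
        lambda: breast_seg.extract_boundaries(
            final_mask, sternum, ev.invasive, original_mask=mask,
            connectivity=config.connectivity,
        ),
    )
    skin = stage(
        "refine_skin",
        {"threshold_ratio": config.threshold_ratio},
        lambda: breast_seg.refine_skin(skin0, dixon_w, fat, config.threshold_ratio),
    )


    tumour_mask = None
    if config.tumour_class != "none":
        if sub_dce is None:
            raise ValidationError("tumour segmentation requires a subtraction DCE volume")
        slice_index = config.tumour_slice
        if slice_index is None:
            slice_index = vols.get("tumour_slice")
        if slice_index is None:
            raise ValidationError("tumour segmentation requires a slice index")

        def do_tumour():
            seed = tumour_seg.select_seed(sub_dce, slice_index, config.manual_seed)
            if config.lower_bound is not None:
                lower = float(config.lower_bound)
            else:
                body = body_mask_otsu(dixon_i)
                lower = tumour_seg.default_lower_bound(
                    sub_dce, body, floor=config.lower_bound_floor
                )
            grown = tumour_seg.grow_tumour(
                sub_dce, seed, tumour_seg.GrowthCriterion(lower), config.connectivity
            )
            labelled = tumour_seg.hoshen_kopelman(grown, config.connectivity)
            largest = tumour_seg.largest_component(labelled)
            out = binary_labelmap(largest, sub_dce)
            if config.remove_roi is not None:
                out = tumour_seg.apply_manual_correction(out, remove_roi=config.remove_roi)
            log.append(
                {"stage": "tumour", "params": {
                    "slice": int(slice_index), "seed": list(seed.index),
                    "manual": seed.manual, "lower_bound": lower}}
            )
            return out

        tumour_mask = stage("tumour_stage", {"slice": int(slice_index)}, do_tumour)

    labels = stage(
        "assemble",
        {},
        lambda: breast_seg.assemble_labelmap(final_mask, skin, chest, tumour_mask),
    )

    gmm = None
    maps: dict[float, DielectricMap] = {}
    fg_vals = np.asarray(dixon_i.data, dtype=float)[labels.data == 1]
    # partial-volume voxels at tumour/boundary rims are far darker than any
    # breast tissue; they would inflate the fitted component variances
    fg_vals = fg_vals[fg_vals >= 0.5 * np.median(fg_vals)]
    if fg_vals.size >= 100:
        gmm = stage(
            "gmm",
            {"seed": config.gmm_seed},
            lambda: dielectric.fit_histogram_gmm(
                fg_vals, seed=config.gmm_seed, predominance_ratio=config.predominance_ratio
            ),
        )
        for f_ghz in config.frequencies_ghz:
            maps[f_ghz] = stage(
                "dielectric",
                {"frequency_ghz": f_ghz, "tumour_class": config.tumour_class},
                lambda f=f_ghz: dielectric.generate_property_maps(
                    labels, dixon_i, f * 1e9, config.tumour_class, gmm
                ),
            )

    result = PipelineResult(
        labels=labels, mask_eval=ev, gmm=gmm, maps=maps, tumour=tumour_mask,
        log=log, intermediates=inter,
    )
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(result.labels, out_dir / "labelmap.nii.gz",
                 provenance={"stage": "assemble", "config": config.to_dict()})
    if result.tumour is not None:
        write_volume(result.tumour, out_dir / "tumour.nii.gz")
    for f_ghz, dmap in result.maps.items():
        tag = f"{f_ghz:g}ghz"
        write_volume(dmap.permittivity, out_dir / f"permittivity_{tag}.nii.gz")
        write_volume(dmap.conductivity, out_dir / f"conductivity_{tag}.nii.gz")
    (out_dir / "mask_evaluation.json").write_text(json.dumps({
        "mse_percent": result.mask_eval.mse_percent,
        "invasive": result.mask_eval.invasive,
        "threshold": result.mask_eval.threshold,
    }, indent=2))
    if result.gmm is not None:
        (out_dir / "gmm.json").write_text(json.dumps(dataclasses.asdict(result.gmm), indent=2))
    (out_dir / "provenance.json").write_text(json.dumps({
        "config": config.to_dict(), "log": result.log}, indent=2, default=str))
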