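# Methods

This note documents the models, the tunable parameters, the numerical
choices, and what the bundled synthetic phantom does and does not
demonstrate. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and label conventions

Volumes are 3D arrays indexed `data[i, j, k]`: axis 0 left→right, axis 1
posterior→anterior, axis 2 inferior→superior (RAS). Voxel indexing is
0-based; world coordinates are `origin + index · spacing` on axis-aligned
grids; all volumes are written as NIfTI-1 with a JSON sidecar (label legend,
provenance). Label maps are signed 8-bit on disk: 0 background, 1
fat + fibroglandular foreground, −1 chest-wall boundary, −2 skin, −3 tumour.
Resampling transforms follow the standard resampling convention (reference
physical space → moving physical space); label maps always resample with
nearest-neighbour interpolation.

## Pre-processing

**Registration** (`register_linear`) is a SimpleITK affine registration
with linear interpolation. The default metric is mean squared intensity
difference, the right choice for the same-modality recovery problems the
package tests (translation recovered within 0.5 voxel, scale within 2%);
Mattes mutual information is available for cross-sequence inputs. In
`run_pipeline` registration is **off by default**: registering a
background-suppressed subtraction volume onto Dixon anatomy is ill-posed
(the two images share almost no structure), and the phantom's sequences are
born co-registered. For real cross-acquisition data set
`PipelineConfig(register=True)`.

**Bias-field correction** (`correct_bias_field`) models the scanner's
smooth multiplicative inhomogeneity. The default estimator fits, in the log
domain, a degree-2 polynomial surface jointly with a piecewise-constant
tissue model: alternate (a) assignment of each voxel to the nearest tissue
class level, (b) a bisquare-reweighted least-squares surface fit to the
class-residuals. Defaults: order 2 (coil profiles are low-order), 3 tissue
classes, 20 iterations. The returned field has mean exactly 1 over the
estimation mask and `corrected * field` reconstructs the input to machine
precision. SimpleITK's N4 is available via `method="n4"`; on this phantom's
piecewise-constant tissues N4 misattributes legitimate tissue contrast to
the field, which is why the polynomial estimator is the default.

`run_pipeline` estimates **one field per exam on the fat-only volume**
(masked to its Otsu foreground, single tissue class) and divides it out of
all four sequences: the Dixon F/W/I triplet comes from a single acquisition
and physically shares one coil profile, and fat is the one tissue with
enormous contrast against everything else in F, which makes the
tissue/field decomposition well posed. Estimating on the in-phase volume
instead is unreliable in the fat-predominant histogram regime, where the
fibroglandular/fat contrast is comparable to the field amplitude and the
class model can trade tissue against field.

**Min–Max normalisation** rescales each sequence onto [0, 255] using the
volume's own extrema (exact affine map, monotone, idempotent). Constant
volumes are rejected (zero dynamic range).

**Median filtering** (3×3×3, edge replication at borders) is applied to the
subtraction volume only, and only when the tumour's largest extent reaches
10 mm — the filter visibly erodes infra-centimetric shapes. The boundary is
inclusive: exactly 10 mm is filtered.

## Breast-region segmentation

1. **Sternum**: first coronal plane, scanning the midline column from
   outside the body, holding a voxel above the water-only volume's mean.
2. **Fat growing**: seed = brightest fat-only voxel anterior to the sternum
   plane; window = [μ+σ, max] of the volume; result = the seed's connected
   component (6-neighbour default, 26 configurable). The intensity window
   is deliberately high — only fat is bright in F.
3. **Watershed split**: when breast and thoracic fat merge through a thin
   leak, a marker-based watershed on the distance transform (markers =
   regions above half the maximum distance) splits the mask; the basin
   containing the posterior-most voxel is discarded (thoracic fat reaches
   deeper posterior than breast fat) and the component containing the
   anterior-most voxel is kept. `run_pipeline` invokes the split only when
   the fat mask leaks more than `watershed_margin_mm` (default 8 mm) behind
   the sternum plane; a healthy fat mask never does, matching the original
   procedure's "only when region growing fails" usage.
4. **Union mask**: dilate the fat mask by a Euclidean radius-3 ball (≈3 mm
   at 1 mm voxels, the reported areolar skin thickness scale), white out
   everything anterior to the sternum plane inside the dilated mask's
   lateral/axial bounding box, multiply by the water-only volume, binarise
   at `mean + std/4` of the product (the threshold must clear the mean but
   stay low enough to close nipple-area holes), and OR with the dilated mask.
5. **Symmetry**: MSE between the mask and its sagittal mirror over **all**
   voxels of the volume, × 100. Above the 10% threshold (configurable) the
   exam is treated as invasive and the mask is completed: union with its
   mirror, keeping one-sided voxels only where the in-phase intensity
   reaches its mean, then morphological hole filling.
6. **Air trim**: the radius-3 dilation inevitably drags a one-voxel air
   shell into the mask. Before contour extraction, mask voxels below the
   in-phase mean (the same statistic the invasive completion uses) are
   returned to the background, so the scan rays land on real skin.
7. **Boundaries**: the 1-voxel mask contour is scanned from the left, right
   and anterior borders (per transverse slice; posterior rays excluded so
   the back is never claimed as skin); the unscanned contour, restricted to
   planes at or behind the sternum, seeds the chest-wall boundary
   (largest connected component, ties broken by smallest linear index).
   Contour component operations use 26-connectivity: a curved one-voxel
   surface is only diagonally connected, and 6-connected labelling
   fragments it. Both contours are thickened by a radius-3 ball and clipped
   by the mask; for invasive exams the symmetric-completion difference
   (final minus original mask) is added to the chest-wall boundary, which
   alone would cover only the invasion notch.
8. **Skin refinement**: multiply the water-only volume by the negated fat
   mask, binarise with the same `mean + std/4` statistic, intersect with
   the dilated skin contour — giving a spatially varying skin thickness.
9. **Assembly**: precedence tumour (−3) > skin (−2) > chest wall (−1) >
   foreground (1) > background (0); the final map is a partition. Tumour
   voxels outside the mask are labelled −3 with a warning.

## Tumour segmentation

Seed = argmax intensity within a user-chosen transverse slice (ties →
smallest linear index), or a manual voxel. The growing window is
[L, seed + (seed − L)] where the lower bound L defaults to μ − 3σ of the
body voxels (body = Otsu foreground of the in-phase volume), clamped to a
floor of 1 on the 0–255 scale — on subtraction images the statistic is
routinely non-positive, so in practice the floor makes the window "anything
clearly above the noise floor connected to the seed", and the subsequent
largest-component step carries the selectivity. Hoshen–Kopelman labelling
is a single raster scan with a path-compressed union-find, relabelled
contiguously in first-occurrence order; it is verified against an
independent BFS flood-fill oracle. `apply_manual_correction` removes or
keeps ROIs (boxes or masks) for cases where a vessel stays attached.

## Dielectric mapping

The two-component Gaussian mixture (scikit-learn EM, 3 restarts, fixed
seed, 500 iterations) decomposes the foreground in-phase histogram; the
brighter component is fat. The histogram counts as **separated** when the
±1σ intervals of the components are disjoint *and* the fibroglandular
weight is at least `predominance_ratio` (default 0.3) of the fat weight.
The weight condition is essential: a fat-predominant exam can have a
vestigial, narrow fibroglandular mode whose fitted interval is disjoint
from fat's, yet its histogram shows no usable separation — this is exactly
the regime the alternative breakpoint table exists for, and under a purely
interval-based rule that table could never apply (its spacing parameter δ
would always degenerate to 0 and the table would be non-monotone).

Separated regime breakpoints: 0, μfg−σfg, μfg, μfg+σfg, μfat−σfat, μfat,
μfat+σfat, image maximum. Fat-predominant regime: the fibroglandular rows
compress to 2μfg−Mfg, μfg, Mfg with Mfg = μfat−σfat−δ and
δ = (Fat_low − (μfg+σfg))/2 clamped at 0. The published definition of δ as
half the Fat_low−Fibroglandular_high gap is circular with Mfg (substituting
forces δ = 0); this resolution reproduces the reference parameter set
self-consistently (δ = 7 for the reported fat-predominant exam). A
non-monotone table raises a configuration error suggesting the other table.

Each breakpoint carries a Debye tissue curve; the voxel map is exact at
breakpoints and affine between them (NumPy interp, clamped outside
[0, max]). Skin and chest-wall voxels take the fixed skin and muscle curve
values; benign tumours behave like lower-adipose-content normal tissue and
reuse the whole-image map; malignant tumours map their own intensity
min/max linearly onto Debye fits of the 25th/75th-percentile malignant
curves — the per-tissue reading, which is what makes the malignant
conductivity bound (7.82 S/m at 6 GHz) exceed the healthy bound (7.38).
Frequencies outside 3–10 GHz are rejected (Debye parameter validity band).
ε₀ = 8.8541878128 × 10⁻¹² F/m. `fit_debye` fixes τ = 13 ps by default (all
shipped tissue rows share it; releasable), minimising joint relative error
of ε_r and σ_eff over the band with per-parameter scaling (τ lives twelve
orders of magnitude below the other parameters).

`run_pipeline` drops foreground voxels darker than half the median
foreground intensity before the histogram fit: they are partial-volume rim
voxels at tumour or boundary edges, far darker than any breast tissue, and
they otherwise inflate the fitted component variances.

## The synthetic phantom

Geometry (default 52×42×34 grid, 0.99×0.99×1 mm voxels): a chest slab with
a thoracic cavity (organs + thoracic fat) behind a pectoral wall; two
hemiellipsoidal breasts (semi-axes 11×22×12 mm) with a 2 mm skin shell;
a retromammary fat layer connecting the two breasts' fat across the
midline (so a single region-growing seed covers both, as subcutaneous fat
does anatomically), stepped at its margins so the mask's chest bottom
slopes inward; prolate fibroglandular blobs plus a thin duct reaching the
skin at the nipple (which leaves the designed hole in the fat mask that the
water-weighted union step must close); a sternum bar at the midline chest
wall. Intensities: fat ≈ 200 in F; fibroglandular/skin/muscle bright in W
(fibroglandular 150, or 165 in the fat-predominant regime so its in-phase
mode crowds fat); I = F + W exactly; tumours enhance only in SUB-DCE
(≈200 over a ≈0.35σ noise floor). A small pure-adipose hotspot (F ≈ 232)
at the left breast base pins the image maximum inside foreground fat, so
the upper anchor of the intensity→property map is deterministically
exercised. Degradations: one order-2 polynomial multiplicative field
(amplitude 0.2, mean 1, shared by all four sequences, returned as ground
truth) and salt-and-pepper noise (density 0.02) on the subtraction volume.

Presets: **benign** (well-separated histogram; 14 mm benign ellipsoid — at
this size the median-filter branch applies; the reported infra-centimetric
benign case would skip it), **malignant** (fat-predominant histogram;
spiculated core with cosine-tapered radial spicules; a thin vessel touches
the tumour for the manual-correction workflow), **invasive** (a large
malignant tumour, ≈30–40 mm with spicules, dark in both Dixon channels,
crossing the pectoral boundary). The invasive tumour is sized analytically
so the mask asymmetry exceeds the 10% rule by construction — with the MSE
denominator spanning the whole volume, only a tumour consuming much of one
breast (as in the reported ≈8 cm invasive case) can do so.

**What passing tests do not show about real data**: the phantom has no MR
acquisition physics, no partial-volume mixing, no coil-dependent noise
correlation, piecewise-constant tissues with Gaussian jitter rather than
textured anatomy, and geometrically ideal skin. Dice scores on the phantom
bound the pipeline's self-consistency, not its clinical accuracy; the
ground-truth conventions for the boundary layers (the chest-wall band under
the breast footprint, the skin shell near the breast region) were defined
once, alongside the generator, to reflect what those labels mean
anatomically.

## Problem sizes and determinism

Tests and the acceptance script run the full pipeline on the default
52×42×34 grid (≈74k voxels), a deliberately compact model that preserves
every geometric feature the method exercises (two breasts, cleft, cavity,
boundary layers, spiculated tumours). All randomness flows from explicit
seeds (phantom rng, GMM restarts, registration sampling); identical inputs
and configuration give bit-identical label maps, and the provenance log of
`run_pipeline` records every stage's parameters.

## Known limitations

- The watershed basin-selection rule assumes thoracic fat reaches deeper
  posterior than breast fat; a mask violating that anatomy would keep the
  wrong side.
- The fat-predominant (Table-2) regime requires a genuinely positive δ;
  exams where the fitted fibroglandular interval overlaps fat's ±1σ
  interval degenerate and raise a configuration error rather than guess.
- Sternum detection keys on the first water-bright plane at the midline; a
  midline skin fold or artifact anterior to the sternum would shift the
  plane.
- The pipeline's shared-field bias model assumes the subtraction volume
  shares the Dixon coil profile; acquisitions with very different fields
  should be corrected independently (`correct_bias_field` per volume).
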