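"""Voxel-wise microwave dielectric property mapping.

A two-component Gaussian mixture fitted to the breast-tissue intensity
histogram positions eight intensity breakpoints; each breakpoint carries a
tissue dielectric-property curve (single-pole Debye dispersion) and voxel
intensities are piecewise-linearly interpolated between adjacent curves to
produce relative permittivity and effective conductivity volumes at a chosen
frequency in the 3-10 GHz validity band.

The single-pole Debye model with static-conductivity term is

    eps*(w) = eps_inf + delta_eps / (1 + j w tau) + sigma_s / (j w eps0)

whose real part gives the relative permittivity and whose imaginary part
gives the effective conductivity sigma_eff = -Im(eps*) w eps0. The 1-pole
Cole-Cole model generalises the relaxation term with a broadening exponent
alpha (alpha = 0 recovers Debye); it is used for the malignant-tumour
literature curves over 0.5-20 GHz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import least_squares
from sklearn.mixture import GaussianMixture

from .errors import DegenerateInputError, FitError, ValidationError
from .volumes import LabelMap, ScalarVolume

#: vacuum permittivity, F/m
EPS0 = 8.8541878128e-12

#: Debye parameters are only valid inside this band
DEBYE_BAND = (3.0e9, 10.0e9)

CURVE_NAMES = (
    "Minimum",
    "Fibroglandular_low",
    "Fibroglandular_median",
    "Fibroglandular_high",
    "Fat_low",
    "Fat_median",
    "Fat_high",
    "Maximum",
)


@dataclass(frozen=True)
class DebyeParams:
    """Single-pole Debye dispersion parameters."""

    eps_inf: float
    delta_eps: float
    tau: float  # seconds
    sigma_s: float  # S/m

    def __post_init__(self):
        if min(self.eps_inf, self.delta_eps, self.sigma_s) < 0 or self.tau <= 0:
            raise ValidationError("Debye parameters must be non-negative with tau > 0")


@dataclass(frozen=True)
class ColeColeParams:
    """1-pole Cole-Cole dispersion parameters (alpha = 0 reduces to Debye)."""

    eps_inf: float
    delta_eps: float
    tau: float
    sigma_s: float
    alpha: float = 0.0

    def __post_init__(self):
        if min(self.eps_inf, self.delta_eps, self.sigma_s) < 0 or self.tau <= 0:
            raise ValidationError("Cole-Cole parameters must be non-negative with tau > 0")
        if not 0.0 <= self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in [0, 1), got {self.alpha}")


def debye_eval(p: DebyeParams, frequency):
    """Relative permittivity and effective conductivity (S/m) at ``frequency`` (Hz)."""
    if np.any(np.asarray(frequency) <= 0):
        raise ValidationError("frequency must be positive")
    w = 2.0 * np.pi * np.asarray(frequency, dtype=float)
    wt2 = (w * p.tau) ** 2
    eps_r = p.eps_inf + p.delta_eps / (1.0 + wt2)
    sigma_eff = p.sigma_s + EPS0 * p.delta_eps * w**2 * p.tau / (1.0 + wt2)
    return eps_r, sigma_eff


def cole_cole_eval(p: ColeColeParams, frequency):
    """Relative permittivity and effective conductivity of the 1-pole Cole-Cole model."""
    if np.any(np.asarray(frequency) <= 0):
        raise ValidationError("frequency must be positive")
    w = 2.0 * np.pi * np.asarray(frequency, dtype=float)
    eps_c = (
        p.eps_inf
        + p.delta_eps / (1.0 + (1j * w * p.tau) ** (1.0 - p.alpha))
        + p.sigma_s / (1j * w * EPS0)
    )
    eps_r = eps_c.real
    sigma_eff = -eps_c.imag * w * EPS0
    return eps_r, sigma_eff


def load_debye_curves() -> dict:
    """Tissue Debye parameters shipped with the package (user-overridable).

    Returns ``{"curves": {name: DebyeParams}, "tumour_percentiles":
    {"25th": DebyeParams, "75th": DebyeParams}, "version": str}``.
    """
    raw = json.loads(
        resources.files("breastmwi").joinpath("data/debye_curves.json").read_text()
    )
    return {
        "version": raw["version"],
        "curves": {k: DebyeParams(**v) for k, v in raw["curves"].items()},
        "tumour_percentiles": {
            k: DebyeParams(**v) for k, v in raw["tumour_percentiles"].items()
        },
    }


# ---------------------------------------------------------------------------
# Debye fitting (Cole-Cole -> Debye conversion)
# ---------------------------------------------------------------------------

def fit_debye(
    curve_samples,
    fit_band: tuple[float, float] = DEBYE_BAND,
    fix_tau: float | None = 13.0e-12,
) -> DebyeParams:
    """Least-squares Debye fit to sampled (frequency, eps_r, sigma_eff) points.

    Minimises the joint relative error of permittivity and conductivity over
    the fit band. The relaxation time defaults to a fixed 13 ps (shared by
    all the tissue curves in the shipped table); pass ``fix_tau=None`` to
    release it.
    """
    samples = np.asarray(
        [(f, e, s) for f, e, s in curve_samples if fit_band[0] <= f <= fit_band[1]],
        dtype=float,
    )
    if len(samples) < 4:
        raise FitError(f"need at least 4 samples inside the fit band, got {len(samples)}")
    freqs, eps_t, sig_t = samples.T

    def model(theta):
        if fix_tau is None:
            ei, de, ss, tau = theta
        else:
            ei, de, ss = theta
            tau = fix_tau
        p = DebyeParams(max(ei, 0.0), max(de, 0.0), max(tau, 1e-15), max(ss, 0.0))
        return debye_eval(p, freqs)

    def residuals(theta):
        eps_m, sig_m = model(theta)
        return np.concatenate(
            [(eps_m - eps_t) / np.maximum(eps_t, 1e-9), (sig_m - sig_t) / np.maximum(sig_t, 1e-9)]
        )

    x0 = [float(eps_t.min()), float(np.ptp(eps_t) + 1.0), float(max(sig_t.min(), 1e-3))]
    bounds_lo, bounds_hi = [0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]
    x_scale = [10.0, 10.0, 1.0]
    if fix_tau is None:
        x0.append(13.0e-12)
        bounds_lo.append(1e-13)
        bounds_hi.append(1e-10)
        x_scale.append(1e-11)  # tau lives twelve orders below the others
    result = least_squares(
        residuals, x0, bounds=(bounds_lo, bounds_hi), x_scale=x_scale,
        xtol=1e-14, ftol=1e-14, max_nfev=2000,
    )
    if not result.success:
        raise FitError("Debye fit did not converge", residuals=result.fun)
    if fix_tau is None:
        ei, de, ss, tau = result.x
    else:
        (ei, de, ss), tau = result.x, fix_tau
    return DebyeParams(float(ei), float(de), float(tau), float(ss))


# ---------------------------------------------------------------------------
# Gaussian mixture of the breast histogram
# ---------------------------------------------------------------------------

@dataclass
class GMMParams:
    """Two-Gaussian decomposition of the breast-tissue intensity histogram.

    The brighter component (in in-phase Dixon images) is fat. ``separated``
    says whether the two modes are resolvable enough for the direct
    breakpoint table; otherwise the fat-predominant table applies, using the
    spacing parameter ``delta`` and the derived upper fibroglandular
    breakpoint ``m_fg``.
    """

    mu_fat: float
    sigma_fat: float
    mu_fg: float
    sigma_fg: float
    weight_fat: float
    weight_fg: float
    separated: bool
    delta: float = 0.0
    m_fg: float = 0.0


def _derive_overlap_params(mu_fat, sigma_fat, mu_fg, sigma_fg) -> tuple[float, float]:
    """delta and M_fg of the fat-predominant breakpoint table.

    delta = (Fat_low - (mu_fg + sigma_fg)) / 2 clamped to >= 0, then
    M_fg = mu_fat - sigma_fat - delta. (The published definition of delta is
    circular with M_fg; this resolution reproduces the reference parameter
    sets self-consistently.)
    """
    fat_low = mu_fat - sigma_fat
    delta = max(0.0, (fat_low - (mu_fg + sigma_fg)) / 2.0)
    m_fg = mu_fat - sigma_fat - delta
    return delta, m_fg


def fit_histogram_gmm(
    intensities,
    seed: int = 0,
    predominance_ratio: float = 0.3,
) -> GMMParams:
    """EM fit of a two-component Gaussian mixture to tissue intensities.

    The component with the larger mean is fat (fat is brightest in in-phase
    Dixon volumes). The histogram counts as *separated* when the +-1 sigma
    intervals of the two components are disjoint and the fibroglandular
    component is not dominated by fat (weight_fg >= predominance_ratio *
    weight_fat); a fat-predominant histogram with a vestigial fibroglandular
    mode engages the alternative breakpoint table even though the fitted
    component intervals may not overlap.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 100:
        raise FitError(f"need at least 100 samples, got {x.size}")
    if float(x.std()) == 0.0:
        raise FitError("degenerate data: all intensities identical")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        random_state=int(seed),
        n_init=3,
        max_iter=500,
        tol=1e-6,
    )
    gm.fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.reshape(-1))
    weights = gm.weights_.ravel()
    fat, fg = (0, 1) if means[0] > means[1] else (1, 0)
    mu_fat, sigma_fat = float(means[fat]), float(sigmas[fat])
    mu_fg, sigma_fg = float(means[fg]), float(sigmas[fg])
    w_fat, w_fg = float(weights[fat]), float(weights[fg])
    disjoint = mu_fg + sigma_fg < mu_fat - sigma_fat
    balanced = w_fg >= predominance_ratio * w_fat
    separated = bool(disjoint and balanced)
    delta = m_fg = 0.0
    if not separated:
        delta, m_fg = _derive_overlap_params(mu_fat, sigma_fat, mu_fg, sigma_fg)
    return GMMParams(
        mu_fat=mu_fat,
        sigma_fat=sigma_fat,
        mu_fg=mu_fg,
        sigma_fg=sigma_fg,
        weight_fat=w_fat,
        weight_fg=w_fg,
        separated=separated,
        delta=delta,
        m_fg=m_fg,
    )


# ---------------------------------------------------------------------------
# Breakpoints and piecewise-linear property mapping
# ---------------------------------------------------------------------------

@dataclass
class BreakpointTable:
    """Ordered (curve name, intensity) pairs of the piecewise-linear mapping."""

    rows: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.rows) != 8:
            raise ValidationError(f"expected exactly 8 breakpoint rows, got {len(self.rows)}")
        intensities = [r[1] for r in self.rows]
        if intensities[0] != 0:
            raise ValidationError("the Minimum breakpoint must sit at intensity 0")
        diffs = np.diff(intensities)
        if not np.all(diffs > 0):
            raise ValidationError(
                "breakpoint intensities must be strictly increasing; the histogram "
                "regime may call for the other breakpoint table"
            )

    @property
    def intensities(self) -> np.ndarray:
        return np.asarray([r[1] for r in self.rows], dtype=float)

    @property
    def curve_names(self) -> list[str]:
        return [r[0] for r in self.rows]


def breakpoints(gmm: GMMParams, max_intensity: float) -> BreakpointTable:
    """Intensity breakpoints of the voxel-intensity -> dielectric-curve map.

    Separated histograms place the six interior rows at mu +/- sigma of each
    component; fat-predominant histograms compress the fibroglandular rows
    using delta and M_fg. Minimum is at 0 and Maximum at the image maximum.
    """
    if max_intensity <= gmm.mu_fat + gmm.sigma_fat:
        raise ValidationError("max_intensity must exceed mu_fat + sigma_fat")
    if gmm.separated:
        interior = [
            ("Fibroglandular_low", gmm.mu_fg - gmm.sigma_fg),
            ("Fibroglandular_median", gmm.mu_fg),
            ("Fibroglandular_high", gmm.mu_fg + gmm.sigma_fg),
            ("Fat_low", gmm.mu_fat - gmm.sigma_fat),
            ("Fat_median", gmm.mu_fat),
            ("Fat_high", gmm.mu_fat + gmm.sigma_fat),
        ]
    else:
        delta, m_fg = gmm.delta, gmm.m_fg
        if delta == 0.0 and m_fg == 0.0:
            delta, m_fg = _derive_overlap_params(
                gmm.mu_fat, gmm.sigma_fat, gmm.mu_fg, gmm.sigma_fg
            )
        interior = [
            ("Fibroglandular_low", 2.0 * gmm.mu_fg - m_fg),
            ("Fibroglandular_median", gmm.mu_fg),
            ("Fibroglandular_high", m_fg),
            ("Fat_low", gmm.mu_fat - gmm.sigma_fat),
            ("Fat_median", gmm.mu_fat),
            ("Fat_high", gmm.mu_fat + gmm.sigma_fat),
        ]
    rows = [("Minimum", 0.0), *interior, ("Maximum", float(max_intensity))]
    return BreakpointTable(rows=rows)


class PiecewiseMap:
    """Piecewise-linear intensity -> (eps_r, sigma_eff) map at one frequency.

    Exact at each breakpoint (the curve value at that frequency), affine in
    between, clamped outside [0, max intensity].
    """

    def __init__(self, bp: BreakpointTable, curves: dict[str, DebyeParams], frequency: float):
        missing = [n for n in bp.curve_names if n not in curves]
        if missing:
            raise KeyError(f"missing dielectric curves: {missing}")
        self.frequency = float(frequency)
        self.intensities = bp.intensities
        vals = [debye_eval(curves[n], frequency) for n in bp.curve_names]
        self.eps_values = np.asarray([v[0] for v in vals], dtype=float)
        self.sigma_values = np.asarray([v[1] for v in vals], dtype=float)

    def __call__(self, intensity):
        x = np.asarray(intensity, dtype=float)
        eps = np.interp(x, self.intensities, self.eps_values)
        sig = np.interp(x, self.intensities, self.sigma_values)
        return eps, sig


def build_piecewise_map(
    bp: BreakpointTable, curves: dict[str, DebyeParams], frequency: float
) -> PiecewiseMap:
    """Construct the piecewise-linear property map for one frequency."""
    return PiecewiseMap(bp, curves, frequency)


# ---------------------------------------------------------------------------
# Property volumes
# ---------------------------------------------------------------------------

@dataclass
class DielectricMap:
    """Voxel-wise relative permittivity and effective conductivity at one frequency."""

    permittivity: ScalarVolume
    conductivity: ScalarVolume
    frequency: float


def generate_property_maps(
    labels: LabelMap,
    dixon_i: ScalarVolume,
    frequency: float,
    tumour_class: str = "none",
    gmm: GMMParams | None = None,
    curve_table: dict | None = None,
) -> DielectricMap:
    """Assign dielectric properties to every voxel of a labelled breast model.

    Foreground voxels (fat + fibroglandular) follow the piecewise-linear map
    of their in-phase intensity; skin and chest-wall voxels take the fixed
    skin and muscle curve values; benign tumours behave like
    lower-adipose-content normal tissue and reuse the whole-image map;
    malignant tumours map their own intensity range linearly onto the
    25th/75th-percentile tumour curves. Background stays at exactly 0.
    """
    if not DEBYE_BAND[0] <= frequency <= DEBYE_BAND[1]:
        raise ValidationError(
            f"frequency {frequency/1e9:.2f} GHz outside the 3-10 GHz Debye validity band"
        )
    if tumour_class not in ("benign", "malignant", "none"):
        raise ValidationError(f"unknown tumour class '{tumour_class}'")
    labels.require_same_grid(dixon_i, "labels and Dixon-I")
    table = curve_table or load_debye_curves()
    curves = table["curves"]
    intensity = np.asarray(dixon_i.data, dtype=float)
    lab = labels.data

    if gmm is None:
        fg_vals = intensity[lab == 1]
        if fg_vals.size < 100:
            raise DegenerateInputError("too few foreground voxels to fit the histogram")
        gmm = fit_histogram_gmm(fg_vals)
    bp = breakpoints(gmm, max_intensity=float(intensity.max()))
    pm = build_piecewise_map(bp, curves, frequency)

    eps = np.zeros(lab.shape, dtype=np.float64)
    sig = np.zeros(lab.shape, dtype=np.float64)

    fg = lab == 1
    if tumour_class == "benign":
        fg = fg | (lab == -3)
    if fg.any():
        eps[fg], sig[fg] = pm(intensity[fg])

    skin = lab == -2
    if skin.any():
        e, s = debye_eval(curves["Skin"], frequency)
        eps[skin], sig[skin] = e, s
    chest = lab == -1
    if chest.any():
        e, s = debye_eval(curves["Muscle"], frequency)
        eps[chest], sig[chest] = e, s

    if tumour_class == "malignant":
        tum = lab == -3
        if tum.any():
            lo_p = table["tumour_percentiles"]["25th"]
            hi_p = table["tumour_percentiles"]["75th"]
            e_lo, s_lo = debye_eval(lo_p, frequency)
            e_hi, s_hi = debye_eval(hi_p, frequency)
            vals = intensity[tum]
            vmin, vmax = float(vals.min()), float(vals.max())
            frac = np.zeros_like(vals) if vmax == vmin else (vals - vmin) / (vmax - vmin)
            eps[tum] = e_lo + frac * (e_hi - e_lo)
            sig[tum] = s_lo + frac * (s_hi - s_lo)

    return DielectricMap(
        permittivity=dixon_i.with_data(eps),
        conductivity=dixon_i.with_data(sig),
        frequency=float(frequency),
    )
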