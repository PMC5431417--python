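"""Contact-indentation elastometry of a thin sheet under a flat punch.

The tissue is much thinner than the indenter diameter, so the deformation
under a flat cylindrical punch of known weight is treated as uniform uniaxial
compression (Hooke's law) rather than a Hertzian/Sneddon contact problem:

    sigma = m * g / A         (stress from the applied weight, kPa)
    eps   = (t0 - t1) / t0    (engineering strain from OCT thickness)
    E     = sigma / eps       (Young's modulus, kPa)

with ``A`` the contact area, preferably measured from the thickness maps and
falling back to the nominal punch area.  The measurement uncertainty budget
covers the four quantities actually measured — indenter mass, indenter
diameter, indenter displacement (thickness change) and sample thickness —
propagated to first order and cross-checkable by a seeded Monte-Carlo oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .morphology import IndentationSite
from .phantom import OCTVolume
from .segmentation import (
    CannyParams,
    ThicknessMap,
    build_thickness_map,
    mask_artifacts,
    mean_thickness,
)

__all__ = [
    "GRAVITY",
    "KPA_PER_CMH2O",
    "Indenter",
    "ErrorBudget",
    "IndentationResult",
    "nominal_contact_area",
    "measured_contact_area",
    "stress_from_load",
    "strain_from_thickness",
    "elastic_modulus",
    "measure_site",
    "nonlinearity_percent",
    "propagate_error_analytic",
    "propagate_error_mc",
    "kpa_to_cmh2o",
]

#: Standard gravitational acceleration, m/s^2.
GRAVITY = 9.80665
#: 1 cmH2O in kPa (display conversion only).
KPA_PER_CMH2O = 0.0980665


def kpa_to_cmh2o(kpa: float) -> float:
    """Convert a stress in kPa to cmH2O for display."""
    return kpa / KPA_PER_CMH2O


@dataclass(frozen=True)
class Indenter:
    """Flat cylindrical indenter: a weighted rod resting on the tissue."""

    diameter: float = 3.0  # mm
    mass: float = 0.663  # g; default reproduces ~0.92 kPa on the 3-mm punch

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("indenter diameter must be positive")
        if self.mass <= 0:
            raise ValueError("indenter mass must be positive")

    @property
    def nominal_area(self) -> float:
        return nominal_contact_area(self.diameter)


@dataclass(frozen=True)
class ErrorBudget:
    """Standard deviations of the four measured quantities (absolute units)."""

    sd_mass: float = 0.0  # g
    sd_diameter: float = 0.0  # mm
    sd_displacement: float = 0.0  # mm (uncertainty of t0 - t1)
    sd_thickness: float = 0.0  # mm (uncertainty of t0)

    def __post_init__(self) -> None:
        if min(self.sd_mass, self.sd_diameter, self.sd_displacement, self.sd_thickness) < 0:
            raise ValueError("all budget SDs must be non-negative")


@dataclass
class IndentationResult:
    """One modulus measurement at one site, with all intermediates."""

    site: IndentationSite
    contact_area: float  # mm^2
    stress: float  # kPa
    thickness0: float  # mm, uncompressed mean
    thickness1: float  # mm, compressed mean
    strain: float
    modulus: float  # kPa
    modulus_sd: Optional[float] = None  # kPa
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.strain < 1:
            raise ValueError("strain must lie strictly between 0 and 1")
        if self.thickness1 >= self.thickness0:
            raise ValueError("compressed thickness must be below uncompressed")
        if not math.isclose(self.modulus, self.stress / self.strain, rel_tol=1e-9):
            raise ValueError("modulus must equal stress / strain")


def nominal_contact_area(diameter: float) -> float:
    """Face area of a flat cylindrical punch: pi d^2 / 4, mm^2."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return math.pi * diameter * diameter / 4.0


def measured_contact_area(
    map_compressed: ThicknessMap,
    map_uncompressed: ThicknessMap,
    indenter: Indenter,
) -> tuple[float, bool]:
    """Contact area from the lateral extent of detected compression, mm^2.

    Counts co-registered unmasked positions whose thickness decreased by more
    than two axial pitches and multiplies by the lateral pixel area.  The
    result is clipped to [0.5, 1.5] x the nominal punch area; outside that
    band a warning is issued and the second return value is True, signalling
    that the nominal area should be preferred.
    """
    if map_compressed.thickness.shape != map_uncompressed.thickness.shape:
        raise ValueError("thickness maps are not on the same lateral grid")
    if map_compressed.lateral_pitch != map_uncompressed.lateral_pitch:
        raise ValueError("thickness maps have different lateral pitches")
    if map_compressed.n_unmasked == 0:
        raise ValueError("compressed map is fully masked")
    ok = ~map_compressed.mask & ~map_uncompressed.mask
    decrease = map_uncompressed.thickness - map_compressed.thickness
    thresh = 2.0 * map_compressed.axial_pitch
    count = int(np.count_nonzero(ok & (decrease > thresh)))
    px, py = map_compressed.lateral_pitch
    area = count * px * py
    nominal = indenter.nominal_area
    lo, hi = 0.5 * nominal, 1.5 * nominal
    clipped = not (lo <= area <= hi)
    if clipped:
        warnings.warn(
            f"measured contact area {area:.3f} mm^2 outside plausible band "
            f"[{lo:.3f}, {hi:.3f}] mm^2; clipping (consider the nominal area)",
            stacklevel=2,
        )
        area = min(max(area, lo), hi)
    return float(area), clipped


def stress_from_load(mass: float, area: float) -> float:
    """Stress under a resting weight: sigma = m g / A in kPa (m in g, A in mm^2)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if area <= 0:
        raise ValueError("area must be positive")
    # g * m/s^2 / mm^2 = mN / mm^2 = kPa
    return mass * GRAVITY / area


def strain_from_thickness(t0: float, t1: float) -> float:
    """Engineering strain (t0 - t1) / t0 of the compressed sheet."""
    if t0 <= 0:
        raise ValueError("uncompressed thickness must be positive")
    if t1 <= 0:
        raise ValueError("compressed thickness must be positive")
    if t1 > t0:
        raise ValueError(
            "compressed thickness exceeds uncompressed (inputs likely swapped)"
        )
    return (t0 - t1) / t0


def elastic_modulus(stress: float, strain: float) -> float:
    """Young's modulus E = sigma / eps for the thin-sample uniaxial model."""
    if strain <= 0:
        raise ValueError("strain must be positive (thin-sample model undefined)")
    return stress / strain


def measure_site(
    vol0: OCTVolume,
    vol1: OCTVolume,
    site: IndentationSite,
    indenter: Indenter = Indenter(),
    canny: CannyParams = CannyParams(),
    refractive_index: float = 1.0,
    mad_k: float = 5.0,
    budget: Optional[ErrorBudget] = None,
    use_measured_area: bool = False,
) -> IndentationResult:
    """End-to-end modulus measurement from an uncompressed/compressed pair.

    Pipeline: thickness maps (with artefact masking) -> mean thickness in the
    site disc for both states -> strain -> contact area -> stress -> modulus.
    All intermediates are recorded in ``metadata``, including the
    axial-quantization error bound E * pitch / displacement.

    The stress denominator defaults to the nominal punch area: the tissue
    drapes smoothly from compressed to free across a wide transition ring, so
    thresholding the thickness decrease systematically overestimates the true
    contact footprint.  The measured area is still computed and recorded as a
    quality check; set ``use_measured_area`` to prefer it when it falls
    inside its plausibility band (the nominal area remains the fallback).
    """
    if vol0.intensity.shape != vol1.intensity.shape:
        raise ValueError("volume pair is not co-registered (shapes differ)")
    map0 = mask_artifacts(build_thickness_map(vol0, canny, refractive_index), mad_k)
    map1 = mask_artifacts(build_thickness_map(vol1, canny, refractive_index), mad_k)
    t0, sd_t0, n0 = mean_thickness(map0, site.center, site.radius)
    t1, sd_t1, n1 = mean_thickness(map1, site.center, site.radius)
    if t1 >= t0:
        raise ValueError(
            f"no detectable compression at site {site.label}: "
            f"compressed mean {t1:.4f} mm >= uncompressed {t0:.4f} mm"
        )
    strain = strain_from_thickness(t0, t1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        area_meas, clipped = measured_contact_area(map1, map0, indenter)
    if use_measured_area and not clipped:
        area = area_meas
    else:
        area = indenter.nominal_area
    stress = stress_from_load(indenter.mass, area)
    modulus = elastic_modulus(stress, strain)
    displacement = t0 - t1
    meta = {
        "site": site.label,
        "n_positions": (n0, n1),
        "thickness_sd_mm": (sd_t0, sd_t1),
        "area_measured_mm2": area_meas,
        "area_measured_clipped": clipped,
        "area_used_mm2": area,
        "displacement_mm": displacement,
        "quantization_error_bound_kpa": modulus * map0.axial_pitch / displacement,
        "stress_cmh2o": kpa_to_cmh2o(stress),
    }
    result = IndentationResult(
        site=site,
        contact_area=area,
        stress=stress,
        thickness0=t0,
        thickness1=t1,
        strain=strain,
        modulus=modulus,
        metadata=meta,
    )
    if budget is not None:
        result.modulus_sd = propagate_error_analytic(result, indenter, budget)
    return result


def nonlinearity_percent(low: IndentationResult, high: IndentationResult) -> float:
    """Apparent stiffening between a low- and high-stress measurement, percent.

    100 * (E_high / E_low - 1); negative values mean apparent softening.
    """
    if high.stress <= low.stress:
        raise ValueError("high-stress result must have the larger stress")
    return 100.0 * (high.modulus / low.modulus - 1.0)


def propagate_error_analytic(
    result: IndentationResult, indenter: Indenter, budget: ErrorBudget
) -> float:
    """First-order error propagation of the modulus, kPa.

    With E = (4 m g / (pi d^2)) * (t0 / delta), delta = t0 - t1, and the four
    measured inputs (m, d, t0, delta) treated as independent:

        SD_E = E * sqrt((SD_m/m)^2 + (2 SD_d/d)^2 + (SD_t0/t0)^2
                        + (SD_delta/delta)^2)
    """
    delta = result.thickness0 - result.thickness1
    if delta <= 0:
        raise ValueError("displacement must be positive")
    terms = (
        (budget.sd_mass / indenter.mass) ** 2
        + (2.0 * budget.sd_diameter / indenter.diameter) ** 2
        + (budget.sd_thickness / result.thickness0) ** 2
        + (budget.sd_displacement / delta) ** 2
    )
    return result.modulus * math.sqrt(terms)


def propagate_error_mc(
    result: IndentationResult,
    indenter: Indenter,
    budget: ErrorBudget,
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo SD of the modulus under Gaussian input perturbations, kPa.

    Independent oracle for :func:`propagate_error_analytic`: perturbs
    (m, d, t0, delta), recomputes E = 4 m g t0 / (pi d^2 delta) per draw and
    returns the sample SD.  Draws with non-positive m, d, t0 or delta are
    rejected and counted; above 1% rejections a warning is attached.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000")
    delta0 = result.thickness0 - result.thickness1
    if (budget.sd_mass, budget.sd_diameter, budget.sd_displacement, budget.sd_thickness) == (0.0, 0.0, 0.0, 0.0):
        return 0.0
    rng = np.random.default_rng(seed)
    m = rng.normal(indenter.mass, budget.sd_mass, n_draws)
    d = rng.normal(indenter.diameter, budget.sd_diameter, n_draws)
    t0 = rng.normal(result.thickness0, budget.sd_thickness, n_draws)
    delta = rng.normal(delta0, budget.sd_displacement, n_draws)
    ok = (m > 0) & (d > 0) & (t0 > 0) & (delta > 0)
    n_rej = int(n_draws - np.count_nonzero(ok))
    if n_rej > 0.01 * n_draws:
        warnings.warn(
            f"{n_rej}/{n_draws} Monte-Carlo draws rejected (non-physical); "
            "the Gaussian budget is too wide for first-order comparison",
            stacklevel=2,
        )
    E = 4.0 * m[ok] * GRAVITY * t0[ok] / (math.pi * d[ok] ** 2 * delta[ok])
    if E.size < 2:
        return 0.0
    return float(np.std(E, ddof=1))
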