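"""Synthetic OCT volumes of a thin elastic sheet under a flat cylindrical punch.

The phantom emulates a thin scattering tissue sheet (nominally ~0.5 mm, the
scale of a mouse diaphragm) imaged by spectral-domain OCT at 8 µm axial and
11 µm lateral resolution, optionally compressed by a flat 3-mm cylindrical
indenter.  The sheet is a piecewise-uniform elastic slab: within the punch
footprint the true engineering strain is

    eps*(sigma) = sigma / E_eff(sigma),    E_eff(sigma) = E * (1 + beta*sigma)

with ``E`` the small-strain Young's modulus (kPa) and ``beta`` a stress-
stiffening coefficient (kPa^-1).  Outside the footprint the thickness is
unchanged; a cosine taper one punch radius wide bridges the two regions.
Speckle is modelled as multiplicative gamma-distributed noise with a
configurable contrast (coefficient of variation), and reflectivity decays
axially by Beer-Lambert attenuation.  Every random element is seeded, so a
(spec, seed) pair renders bit-identical volumes.

Ground truth (surface positions, thickness at any stress) is closed form and
exposed through :func:`true_thickness`, which downstream segmentation and
modulus-recovery tests use as their oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "AdiposeRegion",
    "FibroticLayers",
    "PhantomSpec",
    "PhantomScene",
    "OCTVolume",
    "make_phantom",
    "render_oct",
    "true_thickness",
    "true_strain",
    "pore_density_for_fraction",
]

#: Reflectivity of the medium surrounding the sheet (saline/air background).
BACKGROUND_REFLECTIVITY = 0.02
#: Reflectivity inside adipose pores (lipid voids scatter weakly).
PORE_REFLECTIVITY = 0.05
#: Axial margin of background above and below the sheet, mm.
AXIAL_MARGIN = 0.12
#: Default punch diameter, mm (flat cylindrical indenter).
DEFAULT_PUNCH_DIAMETER = 3.0


@dataclass(frozen=True)
class AdiposeRegion:
    """Lateral disc in which low-reflectivity spherical pores are scattered.

    Pores follow a seeded Poisson point process of intensity ``pore_density``
    (pores/mm^3) through the full sheet depth; each pore is a sphere of radius
    ``pore_radius`` (mm).  The expected pore volume fraction is
    ``1 - exp(-density * 4/3 pi r^3)`` (overlaps allowed).
    """

    center: tuple[float, float]  # lateral (x, y), mm
    radius: float  # mm
    pore_density: float  # pores / mm^3
    pore_radius: float  # mm

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("adipose region radius must be positive")
        if self.pore_density < 0:
            raise ValueError("pore density must be non-negative")
        if self.pore_radius <= 0:
            raise ValueError("pore radius must be positive")


@dataclass(frozen=True)
class FibroticLayers:
    """Axially periodic reflectivity banding mimicking layered fibrosis."""

    band_period: float  # mm, axial period in material coordinates
    band_contrast: float  # dimensionless modulation amplitude in [0, 1]

    def __post_init__(self) -> None:
        if self.band_period <= 0:
            raise ValueError("band period must be positive")
        if not 0 <= self.band_contrast <= 1:
            raise ValueError("band contrast must lie in [0, 1]")


def pore_density_for_fraction(volume_fraction: float, pore_radius: float) -> float:
    """Poisson intensity (pores/mm^3) giving an expected pore volume fraction.

    Inverts ``fraction = 1 - exp(-density * v_sphere)`` for overlapping
    spheres of radius ``pore_radius`` mm.
    """
    if not 0 <= volume_fraction < 1:
        raise ValueError("volume fraction must lie in [0, 1)")
    v = 4.0 / 3.0 * math.pi * pore_radius**3
    return -math.log1p(-volume_fraction) / v


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of a synthetic sheet phantom.

    Parameters
    ----------
    true_modulus : float
        Small-strain Young's modulus E, kPa.
    thickness0 : float
        Uncompressed sheet thickness, mm (default 0.5, a typical thin
        diaphragm).
    lateral_extent : tuple of float
        Lateral field of view (x, y), mm.  The default comfortably contains a
        3-mm punch footprint plus its one-radius transition annulus.
    voxel_pitch : tuple of float
        (axial, lateral x, lateral y) sampling pitch, mm.  Defaults match an
        8 µm axial / 11 µm lateral resolution system sampled at resolution.
    speckle_contrast : float
        Coefficient of variation of the multiplicative speckle in [0, 1].
    attenuation : float
        Beer-Lambert intensity attenuation coefficient, mm^-1.
    nonlinearity_beta : float
        Stress-stiffening coefficient beta (kPa^-1); 0 gives linear elasticity.
    punch_diameter : float
        Diameter of the flat cylindrical indenter, mm (centred laterally).
    """

    true_modulus: float  # kPa
    thickness0: float = 0.5  # mm
    lateral_extent: tuple[float, float] = (6.6, 6.6)  # mm
    voxel_pitch: tuple[float, float, float] = (0.008, 0.011, 0.011)  # mm
    axial_resolution: float = 0.008  # mm
    lateral_resolution: float = 0.011  # mm
    speckle_contrast: float = 0.3
    attenuation: float = 0.8  # mm^-1
    nonlinearity_beta: float = 0.0  # kPa^-1
    punch_diameter: float = DEFAULT_PUNCH_DIAMETER  # mm
    adipose_region: Optional[AdiposeRegion] = None
    fibrotic_layers: Optional[FibroticLayers] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.true_modulus <= 0:
            raise ValueError("true_modulus must be positive")
        if self.thickness0 <= 0:
            raise ValueError("thickness0 must be positive")
        if any(p <= 0 for p in self.voxel_pitch):
            raise ValueError("all voxel pitches must be positive")
        if any(e <= 0 for e in self.lateral_extent):
            raise ValueError("lateral extent must be positive")
        if self.voxel_pitch[0] > self.axial_resolution:
            raise ValueError(
                "axial voxel pitch must not exceed the axial resolution "
                "(surface localization would be undersampled)"
            )
        if not 0 <= self.speckle_contrast <= 1:
            raise ValueError("speckle_contrast must lie in [0, 1]")
        if self.attenuation < 0:
            raise ValueError("attenuation must be non-negative")
        if self.nonlinearity_beta < 0:
            raise ValueError("nonlinearity_beta must be non-negative")
        if self.punch_diameter <= 0:
            raise ValueError("punch_diameter must be positive")
        if self.adipose_region is not None:
            cx, cy = self.adipose_region.center
            ex, ey = self.lateral_extent
            if not (0 <= cx <= ex and 0 <= cy <= ey):
                raise ValueError(
                    f"adipose region centre {self.adipose_region.center} lies "
                    f"outside the lateral extent {self.lateral_extent}"
                )

    # -- derived grid geometry -------------------------------------------
    @property
    def n_lateral(self) -> tuple[int, int]:
        return (
            int(round(self.lateral_extent[0] / self.voxel_pitch[1])),
            int(round(self.lateral_extent[1] / self.voxel_pitch[2])),
        )

    @property
    def punch_center(self) -> tuple[float, float]:
        return (self.lateral_extent[0] / 2.0, self.lateral_extent[1] / 2.0)

    def lateral_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxel-centre lateral coordinates (x, y) in mm."""
        nx, ny = self.n_lateral
        x = (np.arange(nx) + 0.5) * self.voxel_pitch[1]
        y = (np.arange(ny) + 0.5) * self.voxel_pitch[2]
        return x, y


@dataclass(frozen=True)
class PhantomScene:
    """Realized phantom: material-coordinate reflectivity plus geometry.

    ``reflectivity`` is sampled on the *uncompressed* (material) grid with
    shape (n_axial0, nx, ny); under compression the material column is
    remapped affinely onto the deformed geometry.  ``top_depth`` is the flat
    depth of the beam-entry surface, mm.
    """

    spec: PhantomSpec
    reflectivity: np.ndarray  # (nz0, nx, ny), material coordinates
    top_depth: float  # mm

    def footprint_weight(self, r: np.ndarray | float) -> np.ndarray | float:
        """Compression weight vs lateral distance from the punch axis.

        1 inside the footprint, cosine taper to 0 across one punch radius,
        0 beyond twice the punch radius.  Strictly monotone in r over the
        annulus.
        """
        R = self.spec.punch_diameter / 2.0
        r = np.asarray(r, dtype=float)
        w = np.where(
            r <= R,
            1.0,
            np.where(r >= 2 * R, 0.0, 0.5 * (1.0 + np.cos(np.pi * (r - R) / R))),
        )
        return w if w.shape else float(w)


@dataclass
class OCTVolume:
    """A 3-D OCT intensity volume with voxel pitch metadata.

    ``intensity`` has shape (n_axial, nx, ny) with depth increasing along
    axis 0 from the beam-entry side.  ``voxel_pitch`` is (axial, x, y) in mm.
    """

    intensity: np.ndarray
    voxel_pitch: tuple[float, float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3-D array (axial, x, y)")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must all be finite")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if any(p <= 0 for p in self.voxel_pitch):
            raise ValueError("voxel pitch must be strictly positive")
        self.voxel_pitch = tuple(float(p) for p in self.voxel_pitch)


def effective_modulus(spec: PhantomSpec, applied_stress: float) -> float:
    """Stress-dependent effective modulus E_eff = E (1 + beta * sigma), kPa."""
    return spec.true_modulus * (1.0 + spec.nonlinearity_beta * applied_stress)


def true_strain(spec: PhantomSpec, applied_stress: float) -> float:
    """Engineering strain inside the footprint: sigma / E_eff(sigma)."""
    if applied_stress < 0:
        raise ValueError("applied stress must be non-negative")
    return applied_stress / effective_modulus(spec, applied_stress)


def make_phantom(spec: PhantomSpec) -> PhantomScene:
    """Build the ground-truth scene for a phantom spec.

    The reflectivity field lives on the uncompressed material grid.  A bare
    sheet has unit reflectivity; fibrotic layering multiplies in an axial
    cosine banding; adipose pores overwrite spheres with low reflectivity.
    Pore placement is the only stochastic element and is driven entirely by
    ``spec.rng_seed``.
    """
    pz, px, py = spec.voxel_pitch
    nx, ny = spec.n_lateral
    nz0 = int(math.ceil(spec.thickness0 / pz)) + 1
    refl = np.ones((nz0, nx, ny), dtype=np.float32)

    if spec.fibrotic_layers is not None:
        zm = (np.arange(nz0) + 0.5) * pz  # material depth, mm
        band = 1.0 + spec.fibrotic_layers.band_contrast * np.cos(
            2.0 * np.pi * zm / spec.fibrotic_layers.band_period
        )
        refl *= band[:, None, None].astype(np.float32)

    if spec.adipose_region is not None and spec.adipose_region.pore_density > 0:
        _scatter_pores(refl, spec)

    return PhantomScene(spec=spec, reflectivity=refl, top_depth=AXIAL_MARGIN)


def _scatter_pores(refl: np.ndarray, spec: PhantomSpec) -> None:
    """Carve Poisson-scattered low-reflectivity spheres into ``refl`` in place."""
    region = spec.adipose_region
    assert region is not None
    pz, px, py = spec.voxel_pitch
    nz0, nx, ny = refl.shape
    rng = np.random.default_rng(spec.rng_seed)

    slab_volume = math.pi * region.radius**2 * spec.thickness0  # mm^3
    n_pores = int(rng.poisson(region.pore_density * slab_volume))
    if n_pores == 0:
        return
    # uniform in the lateral disc x full material depth
    rr = region.radius * np.sqrt(rng.random(n_pores))
    th = 2.0 * math.pi * rng.random(n_pores)
    cx = region.center[0] + rr * np.cos(th)
    cy = region.center[1] + rr * np.sin(th)
    cz = spec.thickness0 * rng.random(n_pores)

    rp = region.pore_radius
    kz = int(math.ceil(rp / pz)) + 1
    kx = int(math.ceil(rp / px)) + 1
    ky = int(math.ceil(rp / py)) + 1
    zc = (np.arange(nz0) + 0.5) * pz
    xc = (np.arange(nx) + 0.5) * px
    yc = (np.arange(ny) + 0.5) * py
    for i in range(n_pores):
        iz = int(cz[i] / pz)
        ix = int(cx[i] / px)
        iy = int(cy[i] / py)
        z0, z1 = max(0, iz - kz), min(nz0, iz + kz + 1)
        x0, x1 = max(0, ix - kx), min(nx, ix + kx + 1)
        y0, y1 = max(0, iy - ky), min(ny, iy + ky + 1)
        if z0 >= z1 or x0 >= x1 or y0 >= y1:
            continue
        dz = (zc[z0:z1] - cz[i])[:, None, None]
        dx = (xc[x0:x1] - cx[i])[None, :, None]
        dy = (yc[y0:y1] - cy[i])[None, None, :]
        inside = dz * dz + dx * dx + dy * dy <= rp * rp
        block = refl[z0:z1, x0:x1, y0:y1]
        block[inside] = PORE_REFLECTIVITY


def _thickness_field(scene: PhantomScene, applied_stress: float) -> np.ndarray:
    """Per-lateral-position true thickness (nx, ny) at the given stress, mm."""
    spec = scene.spec
    eps = true_strain(spec, applied_stress)
    if eps >= 1.0:
        raise ValueError(
            f"applied stress {applied_stress} kPa implies strain {eps:.3f} >= 1 "
            "(unphysical collapse)"
        )
    x, y = spec.lateral_coords()
    cx, cy = spec.punch_center
    r = np.hypot(x[:, None] - cx, y[None, :] - cy)
    w = scene.footprint_weight(r)
    return spec.thickness0 * (1.0 - eps * w)


def true_thickness(
    scene: PhantomScene, applied_stress: float, lateral_position: tuple[float, float]
) -> float:
    """Exact geometric thickness (mm) at a lateral position and stress state."""
    spec = scene.spec
    xq, yq = lateral_position
    ex, ey = spec.lateral_extent
    if not (0 <= xq <= ex and 0 <= yq <= ey):
        raise ValueError(
            f"lateral position {lateral_position} outside extent {spec.lateral_extent}"
        )
    eps = true_strain(spec, applied_stress)
    if eps >= 1.0:
        raise ValueError("applied stress implies strain >= 1 (unphysical collapse)")
    cx, cy = spec.punch_center
    r = math.hypot(xq - cx, yq - cy)
    w = float(scene.footprint_weight(r))
    return spec.thickness0 * (1.0 - eps * w)


def render_oct(scene: PhantomScene, applied_stress: float, seed: int) -> OCTVolume:
    """Render the scene to an OCT intensity volume at a given applied stress.

    The beam enters at depth 0; the sheet's beam-side surface sits flat at
    ``scene.top_depth`` and the far (indented) surface at top + thickness.
    Rendering is anti-aliased axially: each voxel takes the fractional overlap
    of its axial slab with the tissue, so interface gradients are centred on
    the true surfaces.  Reflectivity is remapped affinely from material
    coordinates, attenuated by ``exp(-mu * path_in_tissue)``, then multiplied
    by gamma speckle with the specified contrast.
    """
    if applied_stress < 0:
        raise ValueError("applied stress must be non-negative")
    spec = scene.spec
    pz, px, py = spec.voxel_pitch
    nx, ny = spec.n_lateral

    t = _thickness_field(scene, applied_stress)  # (nx, ny)
    top = scene.top_depth
    bottom = top + t
    nz = int(math.ceil((top + spec.thickness0 + AXIAL_MARGIN) / pz))

    z_lo = np.arange(nz, dtype=np.float64)[:, None, None] * pz
    z_hi = z_lo + pz
    zc = z_lo + 0.5 * pz

    # fractional axial overlap of each voxel slab with the tissue
    overlap = np.clip(
        (np.minimum(z_hi, bottom[None]) - np.maximum(z_lo, top)) / pz, 0.0, 1.0
    )

    # material-coordinate lookup of reflectivity (affine remap per column)
    nz0 = scene.reflectivity.shape[0]
    zm = (zc - top) / t[None] * spec.thickness0  # material depth, mm
    im = np.clip((zm / pz).astype(np.int32), 0, nz0 - 1)
    ix = np.arange(nx, dtype=np.int32)[None, :, None]
    iy = np.arange(ny, dtype=np.int32)[None, None, :]
    refl = scene.reflectivity[im, ix, iy]

    base = overlap * refl + (1.0 - overlap) * BACKGROUND_REFLECTIVITY
    path = np.clip(zc - top, 0.0, t[None])  # in-tissue path length, mm
    base *= np.exp(-spec.attenuation * path)

    rng = np.random.default_rng(seed)
    c = spec.speckle_contrast
    if c > 0:
        k = 1.0 / (c * c)
        speckle = rng.gamma(shape=k, scale=1.0 / k, size=base.shape)
        base = base * speckle

    meta = {
        "phantom": {k: v for k, v in asdict(spec).items()},
        "applied_stress_kpa": float(applied_stress),
        "render_seed": int(seed),
        "top_depth_mm": float(top),
        "true_strain": float(true_strain(spec, applied_stress)),
    }
    return OCTVolume(
        intensity=base.astype(np.float32),
        voxel_pitch=spec.voxel_pitch,
        metadata=meta,
    )
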