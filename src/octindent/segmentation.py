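"""Surface segmentation and thickness mapping for layered OCT volumes.

A thin sheet appears in a B-scan as two roughly parallel intensity
interfaces.  Each B-scan is normalized by its maximum (so thresholds are
relative and the result is invariant to global intensity rescaling) and run
through a Canny edge detector; per A-scan column the first edge along depth
is the beam-side (top) surface and the last edge the far (bottom) surface.
Surfaces are median-smoothed over a 3x3 lateral neighbourhood before
differencing into a thickness map, and unreliable positions (fewer than two
edges, or robust outliers in thickness) are masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter
from skimage.feature import canny

from .phantom import OCTVolume

__all__ = [
    "CannyParams",
    "ThicknessMap",
    "detect_surfaces_bscan",
    "build_thickness_map",
    "mask_artifacts",
    "mean_thickness",
]

#: Scale factor turning a median absolute deviation into a robust sigma.
MAD_SIGMA = 1.4826


@dataclass(frozen=True)
class CannyParams:
    """Canny edge-detection parameters for surface extraction.

    Thresholds are fractions of each B-scan's maximum intensity (the slice is
    normalized to [0, 1] before detection), so segmentation does not depend
    on absolute signal level.
    """

    gaussian_sigma: float = 2.0  # voxels
    low_threshold: float = 0.1
    high_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        if not (0 <= self.low_threshold < self.high_threshold <= 1):
            raise ValueError("thresholds must satisfy 0 <= low < high <= 1")


@dataclass
class ThicknessMap:
    """Per-lateral-position surface depths and thickness, with artefact mask.

    All depth/thickness values are in mm (optical path divided by the group
    refractive index).  ``mask`` is True where the estimate is unreliable; at
    unmasked positions ``thickness == bottom_depth - top_depth > 0``.
    """

    top_depth: np.ndarray  # (nx, ny), mm; NaN where invalid
    bottom_depth: np.ndarray  # (nx, ny), mm
    thickness: np.ndarray  # (nx, ny), mm
    mask: np.ndarray  # (nx, ny) bool, True = unreliable
    refractive_index: float = 1.0
    lateral_pitch: tuple[float, float] = (0.011, 0.011)  # (x, y), mm
    axial_pitch: float = 0.008  # mm, physical (already n-corrected)
    no_reliable_tissue: bool = False
    diagnostic: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.refractive_index < 1.0:
            raise ValueError("group refractive index must be >= 1")
        ok = ~self.mask
        if np.any(ok):
            if np.any(self.thickness[ok] < 0):
                raise ValueError("unmasked thickness must be non-negative")
            if np.any(self.bottom_depth[ok] <= self.top_depth[ok]):
                raise ValueError("unmasked bottom surface must lie below top")

    @property
    def n_unmasked(self) -> int:
        return int(np.count_nonzero(~self.mask))

    def lateral_coords(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.thickness.shape
        x = (np.arange(nx) + 0.5) * self.lateral_pitch[0]
        y = (np.arange(ny) + 0.5) * self.lateral_pitch[1]
        return x, y

    def region_indices(self, center: tuple[float, float], radius: float) -> np.ndarray:
        """Boolean (nx, ny) selector for a lateral disc (mm units)."""
        if radius <= 0:
            raise ValueError("region radius must be positive")
        x, y = self.lateral_coords()
        r = np.hypot(x[:, None] - center[0], y[None, :] - center[1])
        return r <= radius


def detect_surfaces_bscan(
    bscan: np.ndarray, params: CannyParams = CannyParams()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Detect top/bottom surface rows in one B-scan (axial x lateral).

    Returns ``(top, bottom, valid)``: per-column axial indices (float, NaN
    where invalid) and a boolean validity flag.  A column is valid when the
    detector finds at least two edge crossings, the first taken as the top
    surface and the last as the bottom.  A constant or empty slice yields all
    columns invalid rather than an exception.
    """
    bscan = np.asarray(bscan, dtype=np.float64)
    if bscan.ndim != 2:
        raise ValueError("B-scan must be 2-D (axial, lateral)")
    nz, nlat = bscan.shape
    if nz < 8:
        raise ValueError("B-scan needs at least 8 axial samples")

    top = np.full(nlat, np.nan)
    bottom = np.full(nlat, np.nan)
    valid = np.zeros(nlat, dtype=bool)

    peak = bscan.max()
    if not np.isfinite(peak) or peak <= 0 or bscan.min() == peak:
        return top, bottom, valid

    img = bscan / peak
    edges = canny(
        img,
        sigma=params.gaussian_sigma,
        low_threshold=params.low_threshold,
        high_threshold=params.high_threshold,
    )
    any_edge = edges.any(axis=0)
    n_edges = edges.sum(axis=0)
    first = edges.argmax(axis=0)
    last = nz - 1 - edges[::-1].argmax(axis=0)
    ok = any_edge & (n_edges >= 2) & (last > first)

    # refine each edge crossing to subvoxel depth at the local axial-gradient
    # peak (parabolic interpolation); displacements under compression can be
    # only a few voxels, so integer localization would quantize the strain
    grad = np.abs(np.gradient(gaussian_filter(img, params.gaussian_sigma), axis=0))
    cols = np.nonzero(ok)[0]
    top[cols] = _refine_subvoxel(grad, first[cols], cols)
    bottom[cols] = _refine_subvoxel(grad, last[cols], cols)
    bad = ~(bottom > top)  # refinement must preserve ordering
    top[bad] = np.nan
    bottom[bad] = np.nan
    valid[:] = ok & ~bad
    return top, bottom, valid


def _refine_subvoxel(grad: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Subvoxel edge depth: local |gradient| peak near each (row, col) seed.

    Searches +/-2 voxels around the Canny edge row for the gradient-magnitude
    maximum, then applies three-point parabolic interpolation.
    """
    nz = grad.shape[0]
    if rows.size == 0:
        return np.empty(0)
    offsets = np.arange(-2, 3)
    cand = np.clip(rows[None, :] + offsets[:, None], 0, nz - 1)
    vals = grad[cand, cols[None, :]]
    peak = cand[vals.argmax(axis=0), np.arange(rows.size)]
    k = np.clip(peak, 1, nz - 2)
    gm1 = grad[k - 1, cols]
    g0 = grad[k, cols]
    gp1 = grad[k + 1, cols]
    denom = gm1 - 2.0 * g0 + gp1
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (gm1 - gp1) / denom
    delta = np.where(np.isfinite(delta) & (np.abs(delta) <= 1.0), delta, 0.0)
    return k + delta


def _median3x3_nan(a: np.ndarray) -> np.ndarray:
    """3x3 lateral nan-median with edge padding; NaN where no finite neighbour."""
    padded = np.pad(a, 1, mode="constant", constant_values=np.nan)
    windows = sliding_window_view(padded, (3, 3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        return np.nanmedian(windows, axis=(2, 3))


def build_thickness_map(
    volume: OCTVolume,
    params: CannyParams = CannyParams(),
    refractive_index: float = 1.0,
) -> ThicknessMap:
    """Segment every B-scan of a volume into a thickness map.

    Axial distances are converted from optical to physical length by dividing
    by the group refractive index (the whole depth axis is rescaled by 1/n;
    with the default n = 1 the optical and physical pitch coincide).  Surface
    index maps are median-filtered over a 3x3 lateral neighbourhood before
    differencing.  Columns where edge detection failed are masked; if nothing
    survives the map carries ``no_reliable_tissue`` and a diagnostic.
    """
    if refractive_index < 1.0:
        raise ValueError("group refractive index must be >= 1")
    inten = volume.intensity
    nz, nx, ny = inten.shape
    pz = volume.voxel_pitch[0] / refractive_index

    top_idx = np.full((nx, ny), np.nan)
    bot_idx = np.full((nx, ny), np.nan)
    valid = np.zeros((nx, ny), dtype=bool)
    for j in range(ny):
        t, b, v = detect_surfaces_bscan(inten[:, :, j], params)
        top_idx[:, j] = t
        bot_idx[:, j] = b
        valid[:, j] = v

    top_s = _median3x3_nan(top_idx)
    bot_s = _median3x3_nan(bot_idx)

    thickness = (bot_s - top_s) * pz
    mask = ~valid | ~np.isfinite(thickness) | (thickness <= 0)
    thickness = np.where(mask, np.nan, thickness)

    diag = None
    none_left = not np.any(~mask)
    if none_left:
        diag = (
            "no reliable tissue: no column produced two surface edges "
            "(volume may be thinner than two axial resolution elements)"
        )
    return ThicknessMap(
        top_depth=top_s * pz,
        bottom_depth=bot_s * pz,
        thickness=thickness,
        mask=mask,
        refractive_index=refractive_index,
        lateral_pitch=(volume.voxel_pitch[1], volume.voxel_pitch[2]),
        axial_pitch=pz,
        no_reliable_tissue=none_left,
        diagnostic=diag,
        metadata=dict(volume.metadata),
    )


def mask_artifacts(tmap: ThicknessMap, mad_k: float = 5.0) -> ThicknessMap:
    """Mask robust thickness outliers (artefacts) in addition to invalid columns.

    Positions whose thickness deviates from the unmasked median by more than
    ``mad_k`` robust standard deviations (1.4826 x median absolute deviation)
    are masked.  Masking is monotone in ``mad_k``: lowering it never unmasks.
    """
    if mad_k < 0:
        raise ValueError("mad_k must be non-negative")
    if tmap.n_unmasked == 0:
        raise ValueError("mask_artifacts requires at least one unmasked position")
    ok = ~tmap.mask
    vals = tmap.thickness[ok]
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    dev = np.abs(tmap.thickness - med)
    with np.errstate(invalid="ignore"):
        outlier = dev > mad_k * MAD_SIGMA * mad
    new_mask = tmap.mask | (ok & outlier)
    thickness = np.where(new_mask, np.nan, tmap.thickness)
    none_left = not np.any(~new_mask)
    return replace(
        tmap,
        thickness=thickness,
        mask=new_mask,
        no_reliable_tissue=none_left,
        diagnostic="no reliable tissue after artefact masking" if none_left else tmap.diagnostic,
    )


def mean_thickness(
    tmap: ThicknessMap, center: tuple[float, float], radius: float
) -> tuple[float, float, int]:
    """Mean, SD and count of unmasked thickness within a lateral disc (mm).

    Raises if the disc contains no unmasked position.
    """
    sel = tmap.region_indices(center, radius) & ~tmap.mask
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise ValueError(
            f"no unmasked thickness positions within radius {radius} mm of {center}"
        )
    vals = tmap.thickness[sel]
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return mean, sd, n
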