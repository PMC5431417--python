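"""Region selection and texture metrics on OCT thickness maps and volumes.

Operationalizes three visual assessments used when indenting thin tissue:

* flat-region selection — indentation sites are placed where the thickness
  map shows the least surface heterogeneity, quantified as the local SD of
  thickness in a lateral disc window;
* adipose detection — fatty tissue shows a porous, spongy appearance; the
  porosity fraction is the share of intra-tissue voxels darker than a
  relative threshold of the regional median intensity;
* fibrotic-layering detection — layered fibrosis produces a periodic axial
  banding; the layering index is the height of the largest non-zero-lag peak
  of the mean axial autocorrelation of intra-tissue intensity.

Scores map to boolean flags via configurable thresholds so that cohorts of
phantoms can be classified and fed to contingency-table statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import convolve

from .phantom import OCTVolume
from .segmentation import ThicknessMap

__all__ = [
    "IndentationSite",
    "TextureReport",
    "flatness_map",
    "select_site",
    "porosity_fraction",
    "layering_index",
    "texture_report",
    "DEFAULT_POROSITY_FLAG_THRESHOLD",
    "DEFAULT_LAYERING_FLAG_THRESHOLD",
]

DEFAULT_POROSITY_FLAG_THRESHOLD = 0.1
DEFAULT_LAYERING_FLAG_THRESHOLD = 0.15
#: Default punch radius, mm — the natural site radius for a 3-mm indenter.
DEFAULT_SITE_RADIUS = 1.5

SITE_LABELS = ("left_lateral", "right_lateral", "anterior")


@dataclass(frozen=True)
class IndentationSite:
    """A candidate indentation location on the lateral grid.

    ``flatness_score`` is the local SD of thickness (mm) in the selection
    window; lower is flatter.
    """

    label: str
    center: tuple[float, float]  # lateral (x, y), mm
    radius: float = DEFAULT_SITE_RADIUS  # mm
    flatness_score: float = 0.0  # mm

    def __post_init__(self) -> None:
        if self.label not in SITE_LABELS:
            raise ValueError(f"label must be one of {SITE_LABELS}, got {self.label!r}")
        if self.radius <= 0:
            raise ValueError("site radius must be positive")
        if self.flatness_score < 0:
            raise ValueError("flatness score must be non-negative")


@dataclass(frozen=True)
class TextureReport:
    """Texture scores and their thresholded classification flags."""

    porosity_fraction: float  # in [0, 1]
    layering_index: float  # >= 0
    layering_peak_lag_mm: Optional[float]
    adipose: bool
    layered: bool
    porosity_threshold: float = DEFAULT_POROSITY_FLAG_THRESHOLD
    layering_threshold: float = DEFAULT_LAYERING_FLAG_THRESHOLD


def _disc_kernel(radius_px_x: float, radius_px_y: float) -> np.ndarray:
    nx = int(math.floor(radius_px_x))
    ny = int(math.floor(radius_px_y))
    x = np.arange(-nx, nx + 1)
    y = np.arange(-ny, ny + 1)
    d2 = (x[:, None] / max(radius_px_x, 1e-12)) ** 2 + (
        y[None, :] / max(radius_px_y, 1e-12)
    ) ** 2
    return (d2 <= 1.0).astype(float)


def flatness_map(tmap: ThicknessMap, window_radius: float) -> np.ndarray:
    """Local SD of unmasked thickness in a disc window of ``window_radius`` mm.

    Returns an (nx, ny) score grid; positions where less than half the window
    is unmasked get NaN (no score).
    """
    px, py = tmap.lateral_pitch
    if window_radius < min(px, py):
        raise ValueError("window radius must be at least one lateral pitch")
    kernel = _disc_kernel(window_radius / px, window_radius / py)
    ksize = kernel.sum()

    valid = (~tmap.mask).astype(float)
    t = np.where(tmap.mask, 0.0, tmap.thickness)
    cnt = convolve(valid, kernel, mode="constant", cval=0.0)
    s1 = convolve(t, kernel, mode="constant", cval=0.0)
    s2 = convolve(t * t, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = np.maximum(s2 / cnt - mean * mean, 0.0)
        score = np.sqrt(var)
    score[cnt < 0.5 * ksize] = np.nan
    return score


def select_site(
    tmap: ThicknessMap,
    candidate_region: tuple[tuple[float, float], float],
    window_radius: float,
    label: str,
    site_radius: float = DEFAULT_SITE_RADIUS,
) -> IndentationSite:
    """Pick the flattest scored position inside a candidate disc region.

    Ties are broken by smallest lateral distance to the region centre, then
    by lowest flattened grid index, so the choice is deterministic and
    independent of traversal order.
    """
    (rcx, rcy), rradius = candidate_region
    scores = flatness_map(tmap, window_radius)
    in_region = tmap.region_indices((rcx, rcy), rradius)
    cand = in_region & np.isfinite(scores)
    if not np.any(cand):
        raise ValueError(
            f"candidate region centred at ({rcx}, {rcy}) contains no scored position"
        )
    x, y = tmap.lateral_coords()
    dist = np.hypot(x[:, None] - rcx, y[None, :] - rcy)
    idx = np.nonzero(cand.ravel())[0]
    order = np.lexsort((idx, dist.ravel()[idx], scores.ravel()[idx]))
    best = idx[order[0]]
    i, j = np.unravel_index(best, scores.shape)
    return IndentationSite(
        label=label,
        center=(float(x[i]), float(y[j])),
        radius=site_radius,
        flatness_score=float(scores[i, j]),
    )


def _tissue_voxels(
    volume: OCTVolume, site: IndentationSite, tmap: ThicknessMap
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intensities of interior tissue voxels in site columns.

    Returns (intensity matrix (nz, ncols) masked outside tissue with NaN,
    per-column top row, per-column bottom row).  Only unmasked columns inside
    the site disc participate; the first and last tissue voxel of each column
    are dropped to avoid partial-volume boundary samples.  Requires >= 50%
    unmasked coverage of the site disc.
    """
    disc = tmap.region_indices(site.center, site.radius)
    ok = disc & ~tmap.mask
    coverage = np.count_nonzero(ok) / max(np.count_nonzero(disc), 1)
    if coverage < 0.5:
        raise ValueError(
            f"site {site.label}: unmasked coverage {coverage:.2f} below 50%"
        )
    pz = volume.voxel_pitch[0]
    n = tmap.refractive_index
    cols = np.nonzero(ok.ravel())[0]
    ii, jj = np.unravel_index(cols, ok.shape)
    # back to voxel indices on the volume's axial grid
    top = np.ceil(tmap.top_depth[ii, jj] * n / pz).astype(int) + 1
    bot = np.floor(tmap.bottom_depth[ii, jj] * n / pz).astype(int) - 1
    nz = volume.intensity.shape[0]
    top = np.clip(top, 0, nz - 1)
    bot = np.clip(bot, 0, nz - 1)
    keep = bot > top
    if not np.any(keep):
        raise ValueError("no intra-tissue voxels between the segmented surfaces")
    ii, jj, top, bot = ii[keep], jj[keep], top[keep], bot[keep]
    inten = volume.intensity[:, ii, jj].astype(np.float64)
    rows = np.arange(nz)[:, None]
    inten[(rows < top[None, :]) | (rows > bot[None, :])] = np.nan
    return inten, top, bot


def porosity_fraction(
    volume: OCTVolume,
    site: IndentationSite,
    tmap: ThicknessMap,
    rel_threshold: float = 0.5,
) -> float:
    """Fraction of intra-tissue voxels darker than ``rel_threshold`` x median.

    The median is taken over the same regional voxel population, so the
    fraction is invariant to global intensity rescaling.
    """
    if rel_threshold <= 0:
        raise ValueError("relative threshold must be positive")
    inten, _, _ = _tissue_voxels(volume, site, tmap)
    vals = inten[np.isfinite(inten)]
    if vals.size == 0:
        raise ValueError("no intra-tissue voxels in site")
    med = np.median(vals)
    return float(np.mean(vals < rel_threshold * med))


def layering_index(
    volume: OCTVolume, site: IndentationSite, tmap: ThicknessMap
) -> tuple[float, Optional[float]]:
    """Periodic-banding score of intra-tissue intensity in a site.

    Per column, the intensity between the surfaces is de-meaned; columns are
    truncated to a common length and their autocorrelations averaged.  The
    index is the height of the largest strict local maximum of the normalized
    autocorrelation at non-zero lag; the second value is that peak's lag in
    mm (None when no peak exists).  Constant tissue scores 0.
    """
    inten, top, bot = _tissue_voxels(volume, site, tmap)
    lengths = bot - top + 1
    L = int(np.median(lengths))
    if L < 4:
        raise ValueError("tissue thinner than 4 axial voxels; layering undefined")
    use = lengths >= L
    idx = np.nonzero(use)[0]
    rows = top[idx][None, :] + np.arange(L)[:, None]
    seg = inten[rows, idx[None, :]]  # (L, ncols)
    seg = seg - seg.mean(axis=0, keepdims=True)

    # mean autocorrelation over columns via FFT
    nfft = 2 * L
    spec = np.fft.rfft(seg, n=nfft, axis=0)
    ac = np.fft.irfft(np.abs(spec) ** 2, n=nfft, axis=0)[:L]
    ac = ac.mean(axis=1)
    if ac[0] <= 0:
        return 0.0, None
    ac = ac / ac[0]
    # strict local maxima at lag >= 1
    interior = np.arange(1, L - 1)
    peaks = interior[(ac[interior] > ac[interior - 1]) & (ac[interior] >= ac[interior + 1])]
    if peaks.size == 0:
        return 0.0, None
    best = peaks[np.argmax(ac[peaks])]
    if ac[best] <= 0:
        return 0.0, None
    pz = volume.voxel_pitch[0] / tmap.refractive_index
    return float(ac[best]), float(best * pz)


def texture_report(
    volume: OCTVolume,
    site: IndentationSite,
    tmap: ThicknessMap,
    rel_threshold: float = 0.5,
    porosity_flag_threshold: float = DEFAULT_POROSITY_FLAG_THRESHOLD,
    layering_flag_threshold: float = DEFAULT_LAYERING_FLAG_THRESHOLD,
) -> TextureReport:
    """Combined texture classification of a site: porosity + layering flags."""
    pf = porosity_fraction(volume, site, tmap, rel_threshold)
    li, lag = layering_index(volume, site, tmap)
    return TextureReport(
        porosity_fraction=pf,
        layering_index=li,
        layering_peak_lag_mm=lag,
        adipose=pf > porosity_flag_threshold,
        layered=li > layering_flag_threshold,
        porosity_threshold=porosity_flag_threshold,
        layering_threshold=layering_flag_threshold,
    )
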