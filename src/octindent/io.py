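"""File I/O: TIFF volume stacks with JSON sidecars, CSV/PNG exports.

Volumes travel as multi-page TIFF stacks (one page per axial slice) with a
JSON sidecar of the same stem carrying voxel pitch and provenance metadata.
A missing sidecar falls back to the system default pitch (8 µm axial, 11 µm
lateral) with a logged warning.  Thickness maps export to CSV (one row per
lateral position) and to a PNG heat map with masked positions marked.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .organbath import ForceTrace, MuscleStrip
from .phantom import OCTVolume
from .segmentation import ThicknessMap

__all__ = [
    "DEFAULT_VOXEL_PITCH",
    "write_volume",
    "read_volume",
    "thickness_map_to_csv",
    "thickness_map_to_png",
    "read_strips_csv",
    "write_strips_csv",
    "read_trace_csv",
]

logger = logging.getLogger(__name__)

#: Fallback voxel pitch (axial, x, y) in mm: 8 µm axial / 11 µm lateral.
DEFAULT_VOXEL_PITCH = (0.008, 0.011, 0.011)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(volume: OCTVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF plus JSON sidecar; returns the path."""
    path = Path(path)
    tifffile.imwrite(path, volume.intensity.astype(np.float32))
    sidecar = {
        "voxel_pitch_mm": list(volume.voxel_pitch),
        "shape": list(volume.intensity.shape),
        "metadata": _jsonable(volume.metadata),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_volume(path: str | Path) -> OCTVolume:
    """Read a TIFF stack + sidecar back into an :class:`OCTVolume`.

    Pages must share one shape; a corrupt page is reported by index.  Without
    a sidecar the default pitch is assumed and a warning logged.
    """
    path = Path(path)
    pages = []
    with tifffile.TiffFile(path) as tf:
        shape = None
        for i, page in enumerate(tf.pages):
            try:
                arr = page.asarray()
            except Exception as exc:  # pragma: no cover - corrupt-file details vary
                raise IOError(f"failed to read TIFF page {i} of {path}: {exc}") from exc
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise IOError(
                    f"inconsistent page size at TIFF page {i} of {path}: "
                    f"{arr.shape} != {shape}"
                )
            pages.append(arr)
    if not pages:
        raise IOError(f"no image pages in {path}")
    intensity = np.stack(pages, axis=0)

    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        sidecar = json.loads(sidecar_file.read_text())
        pitch = tuple(sidecar["voxel_pitch_mm"])
        metadata = sidecar.get("metadata", {})
        expected = sidecar.get("shape")
        if expected is not None and list(intensity.shape) != list(expected):
            raise IOError(
                f"{path} truncated or inconsistent: read {intensity.shape[0]} "
                f"pages of {intensity.shape[1:]}, sidecar expects shape "
                f"{tuple(expected)} (first missing page: {intensity.shape[0]})"
            )
    else:
        logger.warning(
            "no sidecar %s: assuming default voxel pitch %s mm",
            sidecar_file,
            DEFAULT_VOXEL_PITCH,
        )
        pitch = DEFAULT_VOXEL_PITCH
        metadata = {}
    return OCTVolume(intensity=intensity, voxel_pitch=pitch, metadata=metadata)


def thickness_map_to_csv(tmap: ThicknessMap, path: str | Path) -> Path:
    """Export a thickness map as CSV: one row per lateral position."""
    path = Path(path)
    nx, ny = tmap.thickness.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x, y = tmap.lateral_coords()
    df = pd.DataFrame(
        {
            "ix": ii.ravel(),
            "iy": jj.ravel(),
            "x_mm": np.repeat(x, ny),
            "y_mm": np.tile(y, nx),
            "top_depth_mm": tmap.top_depth.ravel(),
            "bottom_depth_mm": tmap.bottom_depth.ravel(),
            "thickness_mm": tmap.thickness.ravel(),
            "masked": tmap.mask.ravel().astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def thickness_map_to_png(tmap: ThicknessMap, path: str | Path, dpi: int = 150) -> Path:
    """Render a thickness heat map with masked positions marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    data = np.ma.masked_where(tmap.mask, tmap.thickness)
    ex = tmap.lateral_pitch[0] * tmap.thickness.shape[0]
    ey = tmap.lateral_pitch[1] * tmap.thickness.shape[1]
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(
        data.T * 1000.0,
        origin="lower",
        extent=(0, ex, 0, ey),
        cmap="viridis",
        interpolation="nearest",
    )
    if np.any(tmap.mask):
        mx, my = np.nonzero(tmap.mask)
        x, y = tmap.lateral_coords()
        step = max(1, mx.size // 400)  # keep marker count readable
        ax.plot(x[mx[::step]], y[my[::step]], "r*", ms=3, label="artefact")
        ax.legend(loc="upper right", fontsize=7)
    fig.colorbar(im, ax=ax, label="thickness (µm)")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title("Thickness map")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


STRIP_COLUMNS = ["id", "group", "mass_g", "length_cm", "max_force_gf", "collagen_pct", "fibrosis_score"]


def read_strips_csv(path: str | Path) -> pd.DataFrame:
    """Read an organ-bath strip table; validates each row as a MuscleStrip."""
    df = pd.read_csv(path)
    missing = [c for c in STRIP_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"strip CSV missing required columns: {missing}")
    for _, row in df.iterrows():
        MuscleStrip(
            mass=float(row["mass_g"]),
            fibre_length=float(row["length_cm"]),
            collagen_percent=float(row["collagen_pct"])
            if "collagen_pct" in df.columns and pd.notna(row.get("collagen_pct"))
            else None,
            fibrosis_score=int(row["fibrosis_score"])
            if "fibrosis_score" in df.columns and pd.notna(row.get("fibrosis_score"))
            else None,
        )
    return df


def write_strips_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_trace_csv(path: str | Path) -> ForceTrace:
    """Read a two-column (time_s, force_gf) CSV into a ForceTrace."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("trace CSV needs two columns: time_s, force_gf")
    return ForceTrace(time=df.iloc[:, 0].to_numpy(), force=df.iloc[:, 1].to_numpy())


def _jsonable(obj):
    """Recursively coerce metadata to JSON-serializable plain types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
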