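"""End-to-end measurement pipeline: volume pair -> moduli, textures, report.

Orchestrates segmentation, site selection, texture classification and
modulus measurement for one uncompressed/compressed volume pair, producing a
deterministic JSON report plus a per-site CSV.  Anterior sites are measured
but excluded from the modulus summary by default: anterior regions are where
adipose tissue confounds the modulus, so group summaries use the left and
right lateral sites only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .indentation import measure_site
from .io import read_volume, thickness_map_to_csv, thickness_map_to_png, _jsonable
from .morphology import select_site, texture_report
from .phantom import OCTVolume
from .segmentation import build_thickness_map, mask_artifacts

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

LATERAL_LABELS = ("left_lateral", "right_lateral")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


@_stage("read_volumes")
def _load(vol0_path, vol1_path) -> tuple[OCTVolume, OCTVolume]:
    return read_volume(vol0_path), read_volume(vol1_path)


def run_pipeline(
    config: RunConfig,
    vol0_path: str | Path,
    vol1_path: str | Path,
    write_outputs: bool = True,
) -> dict:
    """Run the full measurement chain on an uncompressed/compressed pair.

    Returns the report dict; when ``write_outputs`` is set, also writes
    ``report.json``, ``results.csv`` and thickness-map CSV/PNG exports under
    ``config.output_dir``.  The report is a pure function of (config, input
    files): rerunning with the same inputs yields byte-identical JSON.
    """
    logger.info("pipeline config: %s", config.model_dump_json())
    vol0, vol1 = _load(vol0_path, vol1_path)

    canny = config.canny.build()
    indenter = config.indenter.build()
    budget = config.error_budget.build()
    thr = config.thresholds

    @_stage("thickness_maps")
    def _maps():
        m0 = mask_artifacts(
            build_thickness_map(vol0, canny, config.refractive_index), thr.mad_k
        )
        m1 = mask_artifacts(
            build_thickness_map(vol1, canny, config.refractive_index), thr.mad_k
        )
        return m0, m1

    map0, map1 = _maps()
    logger.info(
        "thickness maps: %d / %d unmasked positions", map0.n_unmasked, map1.n_unmasked
    )

    ex = vol0.voxel_pitch[1] * vol0.intensity.shape[1]
    ey = vol0.voxel_pitch[2] * vol0.intensity.shape[2]
    center = (ex / 2.0, ey / 2.0)

    sites_out: dict[str, dict] = {}
    lateral_moduli: list[float] = []
    for sc in config.sites:
        region_center = (center[0] + sc.offset_mm[0], center[1] + sc.offset_mm[1])

        @_stage(f"select_site[{sc.label}]")
        def _select(sc=sc, region_center=region_center):
            return select_site(
                map0,
                (region_center, sc.candidate_radius_mm),
                config.flatness_window_mm,
                sc.label,
                site_radius=sc.site_radius_mm,
            )

        site = _select()

        @_stage(f"texture[{sc.label}]")
        def _texture(site=site):
            return texture_report(
                vol0,
                site,
                map0,
                rel_threshold=thr.porosity_rel_intensity,
                porosity_flag_threshold=thr.porosity_flag,
                layering_flag_threshold=thr.layering_flag,
            )

        texture = _texture()

        @_stage(f"measure[{sc.label}]")
        def _measure(site=site):
            return measure_site(
                vol0,
                vol1,
                site,
                indenter=indenter,
                canny=canny,
                refractive_index=config.refractive_index,
                mad_k=thr.mad_k,
                budget=budget,
            )

        result = _measure()
        logger.info(
            "site %s: E = %.3f kPa (stress %.3f kPa, strain %.4f)",
            sc.label,
            result.modulus,
            result.stress,
            result.strain,
        )
        if sc.label in LATERAL_LABELS:
            lateral_moduli.append(result.modulus)
        sites_out[sc.label] = {
            "site": dataclasses.asdict(site),
            "texture": dataclasses.asdict(texture),
            "result": {
                "contact_area_mm2": result.contact_area,
                "stress_kpa": result.stress,
                "thickness0_mm": result.thickness0,
                "thickness1_mm": result.thickness1,
                "strain": result.strain,
                "modulus_kpa": result.modulus,
                "modulus_sd_kpa": result.modulus_sd,
                "metadata": result.metadata,
            },
        }

    summary = {
        "lateral_mean_modulus_kpa": (
            sum(lateral_moduli) / len(lateral_moduli) if lateral_moduli else None
        ),
        "lateral_sites_used": [l for l in LATERAL_LABELS if l in sites_out],
        "anterior_excluded_from_summary": True,
    }
    report = {
        "config": json.loads(config.model_dump_json()),
        "inputs": {
            "vol0": str(vol0_path),
            "vol1": str(vol1_path),
            "shape": list(vol0.intensity.shape),
            "voxel_pitch_mm": list(vol0.voxel_pitch),
        },
        "sites": _jsonable(sites_out),
        "summary": summary,
    }

    if write_outputs:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        rows = [
            {
                "site": label,
                "thickness0_mm": s["result"]["thickness0_mm"],
                "thickness1_mm": s["result"]["thickness1_mm"],
                "strain": s["result"]["strain"],
                "contact_area_mm2": s["result"]["contact_area_mm2"],
                "stress_kpa": s["result"]["stress_kpa"],
                "modulus_kpa": s["result"]["modulus_kpa"],
                "modulus_sd_kpa": s["result"]["modulus_sd_kpa"],
                "porosity_fraction": s["texture"]["porosity_fraction"],
                "layering_index": s["texture"]["layering_index"],
            }
            for label, s in sites_out.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "results.csv", index=False)
        thickness_map_to_csv(map0, outdir / "thickness_uncompressed.csv")
        thickness_map_to_csv(map1, outdir / "thickness_compressed.csv")
        thickness_map_to_png(map0, outdir / "thickness_uncompressed.png")
        thickness_map_to_png(map1, outdir / "thickness_compressed.png")
    return report
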