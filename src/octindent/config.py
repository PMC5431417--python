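"""Validated run configuration for the measurement pipeline.

A :class:`RunConfig` gathers every tunable the pipeline uses — edge-detector
settings, indenter geometry and mass, error budget, texture/artefact
thresholds, refractive index and seeds — in one strictly validated object.
Unknown keys are rejected at load time so silent typos cannot change a run.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .indentation import ErrorBudget, Indenter
from .morphology import (
    DEFAULT_LAYERING_FLAG_THRESHOLD,
    DEFAULT_POROSITY_FLAG_THRESHOLD,
    SITE_LABELS,
)
from .segmentation import CannyParams

__all__ = ["CannyConfig", "IndenterConfig", "BudgetConfig", "ThresholdConfig", "SiteConfig", "RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CannyConfig(_Strict):
    gaussian_sigma: float = Field(2.0, gt=0)
    low_threshold: float = Field(0.1, ge=0, le=1)
    high_threshold: float = Field(0.2, ge=0, le=1)

    def build(self) -> CannyParams:
        return CannyParams(self.gaussian_sigma, self.low_threshold, self.high_threshold)


class IndenterConfig(_Strict):
    diameter_mm: float = Field(3.0, gt=0)
    mass_g: float = Field(0.663, gt=0)

    def build(self) -> Indenter:
        return Indenter(diameter=self.diameter_mm, mass=self.mass_g)


class BudgetConfig(_Strict):
    sd_mass_g: float = Field(0.0, ge=0)
    sd_diameter_mm: float = Field(0.0, ge=0)
    sd_displacement_mm: float = Field(0.0, ge=0)
    sd_thickness_mm: float = Field(0.0, ge=0)

    def build(self) -> ErrorBudget:
        return ErrorBudget(
            sd_mass=self.sd_mass_g,
            sd_diameter=self.sd_diameter_mm,
            sd_displacement=self.sd_displacement_mm,
            sd_thickness=self.sd_thickness_mm,
        )


class ThresholdConfig(_Strict):
    porosity_flag: float = Field(DEFAULT_POROSITY_FLAG_THRESHOLD, ge=0, le=1)
    layering_flag: float = Field(DEFAULT_LAYERING_FLAG_THRESHOLD, ge=0)
    porosity_rel_intensity: float = Field(0.5, gt=0)
    mad_k: float = Field(5.0, ge=0)


class SiteConfig(_Strict):
    """A candidate indentation location, placed relative to the volume centre."""

    label: str
    offset_mm: tuple[float, float] = (0.0, 0.0)  # from lateral centre
    candidate_radius_mm: float = Field(0.4, gt=0)
    site_radius_mm: float = Field(1.5, gt=0)

    @model_validator(mode="after")
    def _check_label(self):
        if self.label not in SITE_LABELS:
            raise ValueError(f"site label must be one of {SITE_LABELS}")
        return self


class RunConfig(_Strict):
    """Full pipeline configuration; every field validated on load."""

    canny: CannyConfig = CannyConfig()
    indenter: IndenterConfig = IndenterConfig()
    error_budget: BudgetConfig = BudgetConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    refractive_index: float = Field(1.0, ge=1.0)
    flatness_window_mm: float = Field(1.5, gt=0)  # default: punch radius
    seed: int = 0
    output_dir: str = "."
    sites: list[SiteConfig] = Field(
        default_factory=lambda: [
            SiteConfig(label="left_lateral", offset_mm=(-0.8, 0.0)),
            SiteConfig(label="right_lateral", offset_mm=(0.8, 0.0)),
            SiteConfig(label="anterior", offset_mm=(0.0, 0.8)),
        ]
    )

    @model_validator(mode="after")
    def _unique_labels(self):
        labels = [s.label for s in self.sites]
        if len(labels) != len(set(labels)):
            raise ValueError("site labels must be unique")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a JSON config file, rejecting unknown keys."""
        data = json.loads(Path(path).read_text())
        return cls.model_validate(data)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.model_dump_json(indent=2))
        return path
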