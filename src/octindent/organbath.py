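"""Organ-bath force normalizations for isolated muscle strips.

Standard in-vitro muscle mechanics: a strip of known mass and optimal fibre
length is stimulated tetanically; peak force (recorded in grams-force) is
normalized to an estimated cross-sectional area assuming a cylindrical strip
of density 1.056 g/cm^3,

    CSA = mass / (density * fibre_length)         [cm^2]
    specific force = F[gf] * 0.00980665 / CSA     [N/cm^2]

A simple composition model predicts how specific force should fall if
contractile muscle were merely replaced by collagen: the healthy-muscle
intercept multiplied by the muscle fraction (1 - %collagen/100).  Observed
cohorts falling below this predicted line indicate impairment beyond simple
loss of contractile mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "MUSCLE_DENSITY",
    "NEWTON_PER_GRAM_FORCE",
    "MuscleStrip",
    "ForceTrace",
    "cross_sectional_area",
    "specific_force",
    "predicted_specific_force",
    "max_tetanic_force",
    "passive_ramp_schedule",
    "RampSchedule",
]

#: Skeletal muscle density, g/cm^3.
MUSCLE_DENSITY = 1.056
#: Newtons per gram-force (standard gravity).
NEWTON_PER_GRAM_FORCE = 0.00980665
#: Default predicted-line intercept: specific force of healthy muscle, N/cm^2.
DEFAULT_INTERCEPT = 24.0


@dataclass(frozen=True)
class MuscleStrip:
    """An organ-bath muscle strip record."""

    mass: float  # g
    fibre_length: float  # cm (optimal length L_o)
    density: float = MUSCLE_DENSITY  # g/cm^3
    collagen_percent: Optional[float] = None  # % of cross-section
    fibrosis_score: Optional[int] = None  # ordinal 0-3

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.fibre_length <= 0:
            raise ValueError("fibre length must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.collagen_percent is not None and not 0 <= self.collagen_percent <= 100:
            raise ValueError("collagen percent must lie in [0, 100]")
        if self.fibrosis_score is not None and self.fibrosis_score not in (0, 1, 2, 3):
            raise ValueError("fibrosis score must be an integer in 0..3")


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled force recording in grams-force."""

    time: np.ndarray  # s, strictly increasing, uniform
    force: np.ndarray  # gf

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if t.ndim != 1 or t.size != f.size or t.size == 0:
            raise ValueError("time and force must be equal-length 1-D arrays")
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("sampling must be uniform")
        if not np.all(np.isfinite(f)):
            raise ValueError("force samples must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "force", f)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else 0.0

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


def cross_sectional_area(strip: MuscleStrip) -> float:
    """Strip cross-sectional area from mass, length and density, cm^2."""
    return strip.mass / (strip.density * strip.fibre_length)


def specific_force(force_gf: float, csa: float) -> float:
    """Force per cross-sectional area, N/cm^2 (force given in grams-force)."""
    if csa <= 0:
        raise ValueError("cross-sectional area must be positive")
    if force_gf < 0:
        raise ValueError("force must be non-negative")
    return force_gf * NEWTON_PER_GRAM_FORCE / csa


def predicted_specific_force(
    collagen_percent: float, intercept: float = DEFAULT_INTERCEPT
) -> float:
    """Composition-model prediction: intercept x muscle fraction, N/cm^2.

    Assumes force scales with the fraction of cross-section that is muscle,
    (1 - %collagen/100); collagen itself produces no active force.
    """
    if not 0 <= collagen_percent <= 100:
        raise ValueError("collagen percent must lie in [0, 100]")
    if intercept < 0:
        raise ValueError("intercept must be non-negative")
    return intercept * (1.0 - collagen_percent / 100.0)


def max_tetanic_force(trace: ForceTrace, plateau_window: float = 0.2) -> float:
    """Maximum plateau force, gf: peak of the moving average over the window.

    Averaging over ``plateau_window`` seconds suppresses stimulus ripple and
    noise spikes so the value reflects the sustained tetanic plateau.
    """
    if plateau_window <= 0:
        raise ValueError("plateau window must be positive")
    if trace.duration < plateau_window:
        raise ValueError("trace shorter than the plateau window")
    n = max(int(round(plateau_window / trace.dt)), 1)
    kernel = np.ones(n) / n
    smoothed = np.convolve(trace.force, kernel, mode="valid")
    return float(smoothed.max())


@dataclass(frozen=True)
class RampSchedule:
    """Linear passive-lengthening schedule in units of L_o."""

    time: np.ndarray  # s
    length: np.ndarray  # cm

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0


def passive_ramp_schedule(
    L0: float,
    start: float = 0.8,
    end: float = 1.1,
    rate: float = 0.05,
    dt: float = 0.01,
) -> RampSchedule:
    """Passive lengthening ramp from start*L0 to end*L0 at ``rate`` L_o/s.

    Defaults give a 6-second ramp from 0.8 to 1.1 L_o at 0.05 L_o/s.
    """
    if L0 <= 0:
        raise ValueError("L0 must be positive")
    if end < start:
        raise ValueError("ramp end must not precede start")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    duration = (end - start) / rate
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    if t.size == 0 or t[-1] < duration:
        t = np.append(t, duration)
    length = L0 * (start + rate * t)
    return RampSchedule(time=t, length=length)
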