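"""Organ-bath normalizations: CSA, specific force, and the composition model.

A muscle strip's force is normalized to its estimated cross-sectional area;
the composition model predicts how specific force would fall if contractile
muscle were simply replaced by collagen.
"""

import numpy as np

from octindent import (
    ForceTrace,
    MuscleStrip,
    cross_sectional_area,
    max_tetanic_force,
    passive_ramp_schedule,
    predicted_specific_force,
    specific_force,
)

strip = MuscleStrip(mass=0.01056, fibre_length=1.0)  # g, cm
csa = cross_sectional_area(strip)
print(f"CSA: {csa:.4f} cm^2 (mass / (1.056 g/cm^3 x length))")

# synthetic tetanic trace: rise, 30-gf plateau, decay
t = np.arange(0, 1.0, 0.001)
force = np.piecewise(
    t, [t < 0.2, (t >= 0.2) & (t < 0.7), t >= 0.7],
    [lambda t: 150 * t, 30.0, lambda t: 30 * np.exp(-(t - 0.7) / 0.05)],
)
peak = max_tetanic_force(ForceTrace(t, force), plateau_window=0.2)
print(f"max tetanic force: {peak:.2f} gf")
print(f"specific force: {specific_force(peak, csa):.2f} N/cm^2")

ramp = passive_ramp_schedule(L0=1.0)  # 0.8 -> 1.1 L_o at 0.05 L_o/s
print(f"passive ramp duration: {ramp.duration:.1f} s")

for collagen in (0.0, 25.0, 50.0):
    print(
        f"predicted specific force at {collagen:4.0f}% collagen: "
        f"{predicted_specific_force(collagen, intercept=24.0):5.1f} N/cm^2"
    )
# Observed cohorts falling below this predicted line indicate impairment
# beyond the simple replacement of muscle by collagen.
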