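"""Propagate measurement uncertainties into a modulus standard deviation.

Four quantities are actually measured: indenter mass, indenter diameter,
indenter displacement (thickness change) and sample thickness.  Their SDs
propagate to the modulus first-order; a seeded Monte-Carlo run provides an
independent check of the analytic formula.
"""

from octindent import (
    ErrorBudget,
    Indenter,
    IndentationResult,
    IndentationSite,
    propagate_error_analytic,
    propagate_error_mc,
)

# a representative measurement: E = 14 kPa at 0.92 kPa and t0 = 0.5 mm
strain = 0.92 / 14.0
result = IndentationResult(
    site=IndentationSite("left_lateral", (1.6, 1.6), 1.5),
    contact_area=7.0686,
    stress=0.92,
    thickness0=0.5,
    thickness1=0.5 * (1 - strain),
    strain=strain,
    modulus=0.92 / strain,
)
indenter = Indenter(diameter=3.0, mass=0.663)
delta = result.thickness0 - result.thickness1

budget = ErrorBudget(
    sd_mass=0.01 * indenter.mass,          # 1% on the weight
    sd_diameter=0.01 * indenter.diameter,  # 1% on the punch diameter
    sd_thickness=0.01 * result.thickness0, # 1% on thickness
    sd_displacement=0.05 * delta,          # 5% on the ~33 um displacement
)

sd_analytic = propagate_error_analytic(result, indenter, budget)
sd_mc = propagate_error_mc(result, indenter, budget, n_draws=100_000, seed=4)
print(f"modulus:             {result.modulus:.2f} kPa")
print(f"analytic SD:         {sd_analytic:.3f} kPa")
print(f"Monte-Carlo SD:      {sd_mc:.3f} kPa")
print(f"relative difference: {100 * abs(sd_mc - sd_analytic) / sd_analytic:.2f}%")
# The displacement term dominates: at ~33 um it is only ~4 axial voxels, so
# thickness precision limits the modulus precision.
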