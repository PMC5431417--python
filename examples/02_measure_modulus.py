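"""Measure Young's modulus from an uncompressed/compressed phantom pair.

The punch carries a weight chosen to apply ~0.92 kPa over its 3-mm face; the
modulus follows from Hooke's law for a thin sheet, E = stress / strain.
"""

from octindent import (
    Indenter,
    IndentationSite,
    PhantomSpec,
    make_phantom,
    measure_site,
    render_oct,
)

spec = PhantomSpec(
    true_modulus=14.0,
    lateral_extent=(3.2, 3.2),
    speckle_contrast=0.3,
    rng_seed=2,
)
scene = make_phantom(spec)
vol0 = render_oct(scene, applied_stress=0.0, seed=21)
vol1 = render_oct(scene, applied_stress=0.92, seed=22)

site = IndentationSite("left_lateral", spec.punch_center, radius=1.5)
result = measure_site(vol0, vol1, site, indenter=Indenter(diameter=3.0, mass=0.663))

print(f"thickness uncompressed: {result.thickness0 * 1000:.1f} um")
print(f"thickness compressed:   {result.thickness1 * 1000:.1f} um")
print(f"strain:                 {result.strain:.4f}")
print(f"stress:                 {result.stress:.3f} kPa"
      f" (~{result.metadata['stress_cmh2o']:.1f} cmH2O)")
print(f"Young's modulus:        {result.modulus:.2f} kPa (truth 14.00 kPa)")
# Strain is the fractional thickness change under the punch; dividing the
# known applied stress by it gives the elastic modulus of the sheet.
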