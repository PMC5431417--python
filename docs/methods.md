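# Methods

## Measurement model

The tissue is modelled as a thin, laterally extensive elastic sheet
compressed by a rigid, flat, cylindrical punch resting under its own
weight.  Because the sheet thickness (~0.5 mm) is small compared with the
punch diameter (3 mm), the deformation under the punch face is treated as
uniform uniaxial compression; the modulus is the ratio of the nominal
stress to the engineering strain, `E = σ/ε` with `σ = m·g/A` and
`ε = (t₀ − t₁)/t₀`.  No Poisson-ratio, substrate or adhesion correction is
applied; this is a deliberate modelling choice for thin sheets, not an
approximation of a Hertz/Sneddon solution.  Strain is engineering strain
(fractional thickness change), not logarithmic strain.

Stress stiffening is modelled through an effective modulus
`E_eff(σ) = E·(1 + β·σ)` with `β ≥ 0` in kPa⁻¹.  A two-stress protocol
(0.92 and 2.4 kPa) quantifies the apparent stiffening as
`100·(E_high/E_low − 1)` percent; `β = 0.065/(2.4 − 1.065·0.92) ≈ 0.0458`
kPa⁻¹ produces a 6.5% increase between those two stresses.

## Phantom simulator

`phantom` renders seeded OCT intensity volumes with closed-form ground
truth.  Key choices:

- **Geometry.** A flat sheet of thickness `t₀` (default 0.5 mm) with the
  punch centred laterally.  Inside the footprint the thickness is
  `t₀·(1 − ε*)` with `ε* = σ/E_eff(σ)`; outside it is unchanged; a cosine
  taper one punch radius wide bridges the two.  The taper is an explicit,
  documented artefact of the phantom (real tissue drapes over a width set
  by its thickness); analysis sites must stay inside the footprint, and
  tests do.
- **Resolution and sampling.** Default voxel pitch 8 µm axial × 11 µm
  lateral, matching a spectral-domain system with 8/11 µm axial/lateral
  resolution sampled at resolution.  The spec requires axial pitch ≤ axial
  resolution so surfaces are not undersampled.
- **Speckle.** Multiplicative gamma noise with shape `1/c²`, giving an
  intensity coefficient of variation exactly `c` (default contrast 0.3).
  This reproduces the edge-degrading effect of speckle on segmentation
  without simulating coherent wave optics.
- **Attenuation.** Beer–Lambert decay `exp(−μ·path)` with default
  μ = 0.8 mm⁻¹, a soft-tissue scale value.
- **Features.** Optional adipose regions (Poisson-scattered low-reflectivity
  spheres; expected void fraction `1 − exp(−λ·v_sphere)`) and fibrotic
  layering (axial cosine banding of the reflectivity in material
  coordinates).  `pore_density_for_fraction` inverts the void-fraction
  relation.
- **Rendering.** Axially anti-aliased: each voxel takes the fractional
  overlap of its slab with the tissue, so intensity gradients are centred
  on the true interfaces; reflectivity is remapped affinely from material
  coordinates under compression.  Identical (spec, seed) pairs render
  bit-identical volumes.
- **Refractive index.** Phantoms are generated in physical units with group
  index n = 1 by default, so the optical and physical axial pitch coincide;
  the segmentation exposes `refractive_index` to exercise the optical→
  physical conversion (the whole depth axis is scaled by 1/n).

What the phantom does *not* emulate: coherent PSF and speckle correlation,
refraction at interfaces, tissue curvature and draping mechanics,
viscoelasticity, heterogeneous stiffness.  Passing tests therefore
demonstrate the correctness of the measurement chain under known geometry
and realistic speckle/attenuation, not performance on real tissue.

## Segmentation

Each B-scan is normalized by its maximum (making all thresholds relative,
and the result invariant to global intensity rescaling) and run through a
Canny detector (defaults: σ = 2 voxels, low/high thresholds 0.1/0.2).  Per
A-scan column the first edge along depth is the top surface and the last
the bottom; columns with fewer than two edges are invalid.  Each edge is
then refined to subvoxel depth by three-point parabolic interpolation of
the axial gradient magnitude around the edge row.  This refinement matters:
at the reference conditions the punch displacement is only ~33 µm ≈ 4
axial voxels (and <2 voxels for a 30 kPa sheet), so integer localization
would quantize the strain with errors up to `pitch/δ` (tens of percent);
with refinement plus averaging over thousands of columns the recovery bias
is below 0.2% across 5–30 kPa.

Surface index maps are median-filtered over a 3×3 lateral neighbourhood
(NaN-aware) before differencing into thickness.  Artefact masking adds a
robust outlier rule: positions deviating from the unmasked median thickness
by more than `mad_k` robust SDs (1.4826×MAD, default `mad_k` = 5) are
masked; masking is monotone in `mad_k`.  A fully masked map carries a
`no_reliable_tissue` flag instead of raising.

## Contact area

The nominal punch area `πd²/4` is the default stress denominator.  An
area measurement from the maps (count of co-registered positions whose
thickness decreased by more than two axial pitches, clipped to
[0.5, 1.5]×nominal with a warning) is computed and recorded as a quality
check, but because the phantom's wide taper region partially exceeds the
decrease threshold, thresholded footprints systematically overestimate the
true contact area; `measure_site` therefore prefers the known punch
geometry and only uses the measured area on explicit request (and then
still falls back to nominal when the estimate leaves its plausibility
band).

## Texture metrics

- **Porosity** = fraction of intra-tissue voxels (surface-adjacent voxels
  excluded) darker than `0.5×` the regional median intensity; adipose flag
  at > 0.10.  Median-relative thresholding makes the score scale-invariant;
  with threshold 1.0 the score is 0.5 by definition of the median.
- **Layering** = height of the largest strict local maximum (non-zero lag)
  of the column-averaged axial autocorrelation of de-meaned intra-tissue
  intensity; layered flag at > 0.15, with the peak lag reported as the band
  period.  Constant tissue scores 0.
- The two scores are not orthogonal: very strong banding (contrast ≥ ~0.5)
  darkens its troughs enough to raise the porosity score.
- **Flat-site selection** scores each lateral position by the SD of
  unmasked thickness in a disc window (default radius = punch radius
  1.5 mm; demos use smaller windows on small phantoms), requiring ≥ 50%
  unmasked coverage; the flattest scored position wins, ties broken by
  distance to the candidate-region centre and then lowest index, so
  selection is deterministic.  Anterior sites are computed but excluded
  from modulus summaries by default, since adipose regions confound the
  modulus.

## Error budget

The four measured quantities are indenter mass, indenter diameter,
displacement `δ = t₀ − t₁`, and thickness `t₀`, treated as independent.
First-order propagation gives
`SD_E = E·sqrt((SD_m/m)² + (2SD_d/d)² + (SD_t₀/t₀)² + (SD_δ/δ)²)`; the
diameter enters twice through the area.  A seeded Monte-Carlo oracle
perturbs the four inputs with Gaussians, recomputes E per draw, rejects
non-physical draws (warning above 1% rejections) and returns the sample SD.

Known limitation: first-order propagation carries O(c²) relative error in
the input CVs.  For this estimator (`E ∝ m·t₀/(d²·δ)`) the exact Gaussian
SD exceeds the first-order value by ≈2% when all relative SDs are 5% and by
≈9.5% when all are 10%, driven by the reciprocal dependences on `d²` and
`δ`.  Agreement to 5% can therefore only be expected while every relative
SD stays below roughly 6%; the test suite documents the 10% corner as a
failing case rather than widening the tolerance.

## Statistics

The 2×2 chi-squared is the uncorrected Pearson statistic `Σ(O−E)²/E` with
marginal-derived expectations — the variant that reproduces published
small-table values exactly; Yates continuity correction is deliberately
omitted.  Pearson correlation is the product-moment formula; Spearman is
Pearson on mid-ranks with ties averaged.  p-values (χ²(1) tail, t
transform) are display conveniences, as are the thin scipy wrappers for
t-tests and Mann-Whitney.

## Organ bath

CSA = mass/(density×fibre length) with muscle density 1.056 g/cm³;
specific force converts grams-force via standard gravity
(0.00980665 N/gf) — the force unit conversion is made explicit because
recordings are in grams.  Maximum tetanic force is the peak of a moving
average over a plateau window (default 0.2 s, an extraction choice).  The
composition model predicts specific force as intercept × (1 −
%collagen/100), default intercept 24 N/cm²; observed cohorts falling below
this line indicate impairment beyond simple muscle replacement.

## Problem sizes and tolerances

Simulation sizes were chosen as the smallest grids that keep every
measurement region geometrically valid: indentation phantoms use a 3.2 mm
lateral field (the 3-mm footprint centred, analysis disc radius 1.5 mm),
segmentation-fidelity and texture phantoms 1–2 mm fields, all at the full
8/11 µm pitch.  Modulus recovery is validated at E ∈ {5, 10, 14, 20, 30}
kPa × 5 seeds (|bias| ≤ 5%, seed SD ≤ 10% asserted; observed ≲ 0.2% and
≲ 0.1%); nonlinearity at 3 seeds (6.5 ± 1.0%); texture separation on
10 + 10 phantoms.  Monte-Carlo error checks use 10⁵ draws.  Numerical
tie-breaks (site selection), degenerate inputs (all-zero slices, fully
masked maps, zero-variance correlations) and determinism contracts are
covered by dedicated tests.
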