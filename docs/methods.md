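# Methods

## Imaging forward model and phantoms

The generator renders a slab radiograph as gray = clip(quantize(g₀ + k·A +
ε)), where A is areal density (g cm⁻²: bulk density × slab thickness for the
slab, 2.83 × step thickness for the wedge, 0 for air), ε ~ N(0, noise_sd) is
detector noise in gray levels, and g₀, k place air at 5% and the thickest
wedge step at 95% of the dynamic range (so the wedge spans >80% of it).
Linearity in areal density is an internal generator choice: it makes the
forward model analytically invertible and therefore testable. The calibration
stage never assumes it — it interpolates through the wedge points, so any
monotone detector response would calibrate exactly as well. Gray polarity
(denser = brighter by default) is a flag so the inverted convention is
exercised by tests.

Phantom geometry: the slab is a horizontal rectangle (default 4.0 × 0.6 cm at
0.01 cm px⁻¹) with the growth-axis track along its mid-line; the wedge sits
below it, 10 steps from 0.09 to 1.08 cm (a stand-in — real wedge geometries
vary, so the steps are configuration); everything else is air. The band
profile maps position along the growth axis to density and defaults to
1.4 + 0.4·sin(2πx/0.8), i.e. annual bands of period 0.8 cm around a typical
massive-coral density.

**Pores are partial-depth voids.** Each pore is a disc that removes a
configurable fraction of the local areal density (`pore_depth_fraction`,
default 0.5; 1.0 gives a through-hole). This is deliberate: a void through
the full slab thickness images exactly at the air gray level and is
background, not porous space — the gray-band porosity measure (below) is
defined on the *intermediate* air/CaCO₃ grays produced by partial-volume
pixels. Discs are rejection-sampled without overlap (≥1 px clearance) until
the requested area fraction is met, which makes the planted count an exact
oracle for particle counting; unreachable fractions raise an error rather
than silently under-filling.

What the phantoms do **not** emulate: scatter, beam hardening, film response
curves, flat-field inhomogeneity, partial-depth pore geometry beyond the
single depth fraction, macroborer galleries. Passing the round-trip tests
therefore shows the calibration/detection chain is correct on an idealized
detector, not that it is robust to every artifact of real film.

## Densitometry

Calibration builds a monotone piecewise-linear interpolant through
(mean step gray, 2.83 × step thickness) with the air background appended at
areal density 0. Strict monotonicity of step grays is required (the error
names the offending steps); direction is arbitrary, so inverted-polarity
images calibrate unchanged. Conversion outside the calibrated range clamps to
the end points and logs a warning. Bulk density = interpolated areal density
/ slab thickness (0.9 cm default, per-slab override in metadata).

The density profile averages gray over `track_width` (default 5) pixels
perpendicular to the local track direction; positions are cumulative path
length × pixel size, starting at 0 at the colony surface. Annual-band
detection smooths the profile with a centered moving average
(`smooth_window_cm`, default 0.05 cm) and finds minima with prominence ≥
`min_prominence` (default 0.05) × the smoothed range. Two robustness measures
matter at realistic noise: minima closer than `min_separation_cm` (default
0.1 cm, far below any annual extension) are treated as one noise-split
boundary, and each minimum is re-localized by a least-squares parabola over
its neighborhood — a single-sample argmin moves by several pixels under
2 gray levels of noise, while the parabola vertex averages that noise away.
The refined position is rounded back to the pixel grid so that band
arithmetic stays index-exact: annual density is the unweighted mean of the
*raw* calibrated densities on the half-open interval between consecutive
minima, extension is the position difference, and consequently the
extension-weighted mean of annual densities reproduces the profile mean over
the covered span to machine precision. Incomplete terminal intervals are
discarded as partial years. Whether annual density should be computed on raw
or smoothed values is not settled usage; raw is the default here because
smoothing is only a detection aid.

## Porosity

Per radiograph (exposure varies between scans), S_max is the mean gray of the
aragonite reference region — by default the wedge step closest to the slab
thickness, so that a solid-aragonite slab pixel images exactly at S_max; a
whole-wedge mean is available as an annotation choice. S_min pools the air
background with wedge pixels of thickness ≤ 0.05 cm (the air/CaCO₃ transition
at the wedge foot; with the default wedge there are no such steps and S_min
is the background mean). Thresholds are normalized so S_min < S_max under
either polarity. Pore space is slab ∩ (S_min < gray < S_max) with *strict*
inequalities: pixels at the reference gray are solid aragonite by
construction, pixels at the air level are background. Components are labeled
at 8-connectivity by default (4 available), components below `min_area`
(default 1 px) are dropped, and the summary reports count, pore-area percent
of the slab, and the calibrated mean slab density.

Note the measurement's domain: on a phantom whose matrix is *bulk* density
< 2.83 everywhere, every matrix pixel lies inside the gray band and the
porosity percent saturates — physically, bulk density below the mineral
density *is* sub-pixel porosity. Discrete pore statistics are therefore
meaningful on slabs whose solid phase images at the reference gray, which is
how the porosity phantoms are built (solid aragonite matrix + planted pores).

## Mixed models

Observational units are annual-band densities; sampling units are colonies.
The model is `density ~ status + band_age (+ status:band_age) +
extension_cm` with REML random intercepts for colony nested in reef zone
(statsmodels MixedLM; groups = zone, colony as a variance component; plain
colony intercepts when only one zone is present). Treating the continuous
extension rate as a "random effect" is not expressible as a random intercept,
so extension enters as a fixed covariate; the divergence is flagged in the
fit metadata. Band age is coded as integer years from the surface (1 = most
recent complete band) and enters as a continuous fixed effect. Residual
autocorrelation structures along the band series (AR1 etc.) are not
implemented. One model per species is the intended use; nothing pools species
by default.

Fits that fail to converge raise (with optimizer diagnostics from the lbfgs →
bfgs → powell cascade) rather than returning silently. Type II Wald χ² tests
respect marginality: a main effect whose interaction is in the model is
tested on a companion fit without that interaction; the interaction itself
(and any term with no higher-order relatives) is a subvector Wald test
β'V⁻¹β on the given fit, so a single-df term's χ² equals (estimate/SE)²
identically. Three-level status designs get all pairwise contrasts of
estimated marginal means at the mean band age, with a Tukey studentized-range
adjustment by default (bonferroni/none selectable; the method label is
recorded in each result).

Calibration at the simulated study conditions (12 colonies × 20 bands,
between-colony SD 0.05 g cm⁻³, residual SD 0.10 g cm⁻³): the status-effect
estimate is unbiased to < 0.005 g cm⁻³ and 95% CI coverage sits near 0.91,
but the Wald χ² null rejection rate is ~9% rather than 5% — the status
comparison is between-colony with ~10 denominator degrees of freedom, and the
χ² reference (used deliberately, as in standard lme4/car practice) has no
small-sample correction. Users with few colonies should read marginal
p-values near 0.05 accordingly.

## Carbonate budget

Volumes: massive/columnar/sub-massive colonies use the elliptical paraboloid
C = (π/2)·H·r². The source convention is dimensionally loose about r ("mean
diameter"); here r = (d_max + d_perp)/4, i.e. the mean radius, which makes
the formula dimensionally consistent. Branching/foliose colonies use
V = 0.11·d_max·d_perp·H; the 0.11 correction factor is an applied constant
derived elsewhere from 3D colony models, not re-derived here. Mass =
volume × density × 1000 (g cm⁻³ ≡ t m⁻³).

Scenario classification is binary: a colony of an SCTLD-susceptible species
dies in the post scenario iff lesions cover > 10% of its surface or recent
mortality is 100%; partial or old mortality below that bar counts as fully
alive in both scenarios. Species without observed dissolution carry
D_d = D_l and contribute exactly zero loss even when killed. Transect values
are colony-mass sums divided by the transect area (default 10 m², the 10 × 1
m belt); reef values are the *mean over transects* (not colony pooling over
summed area — equivalent only for equal-area transects), scaled by reef area
into tonnes; the system percent lost is relative to the pre-event stock of
all species. All computation is double precision; rounding to whole tonnes is
presentation only. Losses are ≤ 0 everywhere by construction. For species
sampled at two post-mortality times, the budget uses the longer-exposure
(2-year) dead density, matching the exposure of the surveyed mortality.

## Synthetic survey generator

Belt transects (10 × 1 m, 10 per reef by default) over a six-reef system
with synthetic areas of 2.1–8.9 × 10⁵ m². The default community holds the
four focal species (three with dissolution, one — the plocoid O. faveolata
stand-in — susceptible but without density loss) plus non-susceptible
space-holders; relative abundances sum to 1 and densities are plausible
synthetic values, not measurements. Colony counts are Poisson (mean 8 per
transect); maximum diameters are log-normal (median 0.25 m, σ = 0.6),
perpendicular diameters uniform 0.6–1.0 of d_max, heights log-normal around
0.6 of d_max. Susceptible colonies are afflicted with probability 0.5
(configurable); afflicted colonies draw lesions of 15–95% or full recent
mortality. The generator emits the tables *and* the true budget computed by
explicit per-colony summation — an implementation-independent oracle for the
budget module. It does not model disease spread, within-reef spatial
structure, or size-dependent affliction.

## Determinism and problem sizes

Every generator takes an explicit seed; the pipeline fans one master seed out
through `numpy.random.SeedSequence` into per-stage child seeds, and identical
config + seed reproduces every output bit-for-bit (outputs embed the seed and
a hash of the scientific configuration). Simulation sizes used by the test
suite and the acceptance script — 100 noisy phantoms for boundary recovery,
50 phantoms for flood-fill equivalence, 200/500 replicates for mixed-model
bias/coverage/type-I, 100 surveys for the budget oracle — are chosen so the
whole suite completes in a few minutes on one CPU while keeping Monte-Carlo
standard errors around a percentage point.

## Known limitations

- Wedge and slab regions must be annotated; no automatic segmentation.
- No flat-field correction, no calendar-year dating of bands.
- Porosity is 2D gray-band porosity, not micro-CT pore morphometrics.
- No uncertainty propagation from the mixed-model density estimates into the
  carbonate budget.
- The Wald χ² status test is liberal below ~15 colonies (see above).
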