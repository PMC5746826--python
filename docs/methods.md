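# Methods

This note records the model behind `fiberweb`, the choices made where the
design was genuinely open, and what the synthetic-data pipeline does and does
not establish.

## The RVE constitutive model

**Idealization.** The membrane is a stack-free planar network: straight,
unbonded fibers of common radius `r` and circular cross-section, axis angles
`α` i.i.d. uniform on `[0, π)` (`ψ(α) = 1/π`), centers uniform over a square
RVE of side `L` and thickness `T`. Fiber lengths form the arithmetic
progression `l_i = i·Δl` with `Δl = 2L/Nf` and `l_Nf = 2L`; the progression
sums to `Σl_i = L(Nf + 1)`. Crimp, fiber–fiber bonding, slippage and
inter-layer interaction are excluded by assumption; the virtual tensile test
is correspondingly a pure force summation, not a structural solve.

**Porosity closure.** The fiber count follows from requiring the fiber
volume to fill the solid fraction of the RVE:

    L²T(1 − P) = πr² Σl_i = πr² L (Nf + 1)
    ⇒  Nf = L T (1 − P) / (πr²) − 1 ,

rounded half-away-from-zero (a count below 1 is a degenerate-geometry
error). With this count every generated network satisfies volume
conservation identically, and `network_porosity ∘ generate_network` returns
the requested porosity to within half a fiber volume (relative error
`≤ 0.5·πr²/(L²T·(1−P))`, about 10⁻⁶ at study scale).

**Membrane stress.** A specimen of width `W = kL` engages the thinned
fraction `τ = W/L` of fibers whose axis lies in the symmetric band
`min(α, π − α) ≤ θ = arctan k` about the tension axis; each carries the
axial force component `F₂₂ = σ_f πr² cos²α`. Averaging `F₂₂` over the
uniform orientation density on that two-sided band and normalizing by the
specimen cross-section `WT` gives

    σ = (1 − P) (sin θ cos θ + θ) / π · σ_f
      = (1 − P) [k + (1 + k²) arctan k] / (π (1 + k²)) · σ_f ,

the package's central relation. The two parameterizations are algebraically
identical and both are property-tested against direct numerical quadrature
of the `cos²` integral. Limits: `σ(k = 0) = 0` exactly (no fiber bridges a
zero-width cut) and `σ → (1 − P)σ_f/2` as `k → ∞`; the ratio `σ/σ_f` never
exceeds `(1 − P)/2`, so the inverse map amplifies stress by at least
`2/(1 − P)`.

The default drops the single-fiber cross-section `πr²` against the membrane
cross-section (relative size `πr²/(LT)`, ~10⁻⁶ at study scale); an exact
mode replaces the solidity `(1 − P)` by `(1 − P) − πr²/(LT)` for users who
want the correction explicit. An optional multiplicative calibration
constant (default 1) is accepted and recorded in output metadata; none is
applied anywhere in this package's own analyses.

**Strain map.** Membrane strain `ε` maps to the strain of a fiber at angle
`α` via `ε_f = ε(cos²α − ν_xy sin²α)`, and at the cutoff angle
`α = arctan k` this is `ε_f = ε(1 − ν_xy k²)/(1 + k²)`. The contraction
coefficient `ν_xy = ε_x/ε_y` is entered as a positive magnitude for a
contracting mat; values above 1 are physical for nonwovens (fibers realign
toward the load) and the study-scale strain data imply `ν_xy ≈ 1.65` near
yield. `ν_xy(ε)` profiles are interpolated piecewise-linearly in axial
strain with constant extrapolation beyond the measured range, since no
functional form is established for fiber mats. The curve-level transform
maps each `(ε, σ)` point independently; it rejects inputs whose mapped
strain axis stops increasing (which happens exactly when `1 − ν_xy k²`
changes sign over the strain range).

## Stochastic network simulator

One integer seed feeds four named `SeedSequence` sub-streams (orientations,
length permutation, centers, specimen thinning), making networks
byte-identical across reruns. Nominal fiber lengths are kept for volume
accounting even where a fiber overhangs the RVE boundary, because the
closure argument uses nominal lengths. Lengths are assigned to orientations
by random permutation — nothing couples the two in the model.

The specimen cut applies (a) an independent thinning with probability
`τ = W/L`, realizing the areal-fraction argument (a literal centered-strip
membership test on fiber centers is available behind a `geometric` flag for
sensitivity analysis), and (b) the symmetric orientation band
`min(α, π−α) ≤ θ`. The thinning variates are drawn at network generation
and stored with the network, so a cut is a deterministic function of the
network object, including after text serialization and reload.

With the porosity-consistent fiber count the force-summation estimator
`σ_MC = Σ σ_f πr² cos²α / (WT)` is unbiased for the closed form at the
network's realized porosity, up to the neglected `πr²` term (relative order
`1/Nf`): the expected participating count is `Nf·τ·2θ/π` and the band
average of `cos²α` is `(sin θ cos θ + θ)/(2θ)`. The acceptance suite checks
the seed-averaged estimate against the closed form to 3 standard errors at
12 `(P, k)` grid points with 10⁵-fiber networks (50 seeds each) — network
thickness is chosen per grid point so the closure count equals 10⁵, keeping
the simulated ensembles at a desk-scale problem size.

## Synthetic micrographs and image-based characterization

**Rendering.** Fibers are drawn as straight bands with analytic
anti-aliasing: candidate pixels are enumerated by scanline spans along the
dominant axis (cost proportional to band area) and each pixel's intensity
is the linear-coverage profile `clip(w/2 + 0.5 − d, 0, 1)` of its exact
distance `d` to the fiber axis, composited with `max` (an upper fiber
occludes a lower one). The 0.5 intensity level therefore sits on the true
band boundary at any orientation — a property the Pillow/PIL wide-line
rasterizer does not have (its oblique wide lines run 1–2 subpixels thin,
which is why rendering is done analytically). Rendering requires the
thinnest fiber to span at least 3 px.

**FOD estimation.** Local orientation comes from the structure tensor:
Gaussian-derivative gradients (σ = 1 px) pooled with a σ = 3 px tensor
window; the dominant eigenvector is the edge normal and the fiber axis is
its perpendicular, folded to `[0°, 180°)` with 0° on the tension (image x)
axis. Foreground pixels are weighted by tensor energy, which concentrates
weight on fiber boundaries and so weights each fiber roughly by its visible
length. This estimator is a documented, reproducible stand-in for
proprietary commercial orientation software; only qualitative agreement
(uniformity of near-uniform mats) is claimed, not equivalence.

**Effective sample size for uniformity testing.** Pixels along one straight
fiber share one orientation, so pixel counts wildly overstate the evidence.
The chi-square uniformity test therefore takes an effective sample size
explicitly; the calibrated choice for a rendered network is the
length-weighted Kish ESS of the generating fibers, `(Σl)²/Σl² ≈ 0.75·Nf`
for the arithmetic progression. The histogram's own default (pixel-weight
ESS) is retained for exploratory use but documented as anti-conservative.
With the fiber-level ESS the test is conservative in practice (the
estimator's angular smoothing spreads mass between neighboring 1° bins,
shrinking the statistic below its nominal chi-square), so non-rejection of
rendered uniform networks is the expected outcome and rejections indicate
genuine anisotropy.

**Diameter measurement.** The foreground (intensity ≥ 0.5) is skeletonized;
local diameter is twice the Euclidean distance transform at retained
skeleton pixels, times the nm-per-px scale. Three pruning rules remove
pixels whose distance value does not measure a single fiber wall-to-wall:
(a) near skeleton junctions and endpoints, within
`2.2·EDT + 2 px` (crossing neighborhoods inflate the local width);
(b) where the distance ball touches the image border (border-clipped wedges
otherwise contribute spuriously thin samples); and (c) fragments shorter
than 3 px. One diameter sample is then taken per retained skeleton
fragment (the fragment mean) rather than per pixel: thick fibers lose more
skeleton length to junction exclusion zones, so pixel-pooling would
under-weight them. No sub-pixel correction constant is applied: on
constructed single-fiber ground truth the two half-pixel discretization
offsets (background pixel centers beyond the wall; skeleton pixels off the
true axis) cancel to within ~0.1 px across band widths of 5–50 px. The
estimator retains a small negative bias (~1–2 %) on crowded multi-fiber
fields from residual junction effects; this is visible in the validation
harness and accepted as-is.

## Synthetic study data

Generator defaults encode the reference study conditions: fiber diameters
lognormal with arithmetic mean 272 nm and CV 29.4 %; membrane porosity
`P = 0.75`; specimen ratio `k = 0.125` (40 mm gauge × 5 mm width, 0.11 mm
thickness); strain rate 0.01 s⁻¹ (metadata only — no rate dependence is
modeled); membrane tensile descriptors of yield 4.11 MPa at strain 0.049,
post-yield slope 2.60 MPa, break strain 0.543.

**Bilinear curves.** The synthetic membrane record is two line segments
meeting at the yield knee, with the knee included as a data point. A single
bilinear curve through the origin cannot carry an elastic modulus different
from the yield secant, nor a break stress different from
`σ_y + s·(ε_b − ε_y)`; the generator therefore honors the knee, post-yield
slope and break strain, and derives `E = σ_y/ε_y` (83.9 MPa at the defaults)
and the break stress (5.39 MPa) from the geometry. Descriptor-recovery tests
compare against these derived truths.

**Micrograph fields.** The diameter study renders 400 lognormal-diameter
fibers, 3 per 768² frame at 10 nm/px (constant fiber length spanning the
frame; sparse fields keep crossing contamination low), measures each frame
and pools the samples — emulating the multi-frame characterization workflow
in which many micrographs are aggregated. The FOD study renders 500-fiber
uniform networks at 68 nm/px on 1536² frames.

**What passing tests do not show.** The synthetic fields are cleaner than
real FE-SEM micrographs in every respect that matters to the estimators: no
detector noise, charging artifacts, beads, or depth-of-field blur; perfectly
straight fibers of known contrast; single-layer geometry rather than a
imaged 3-D stack. Recovery results bound estimator error under the model's
own assumptions only. Similarly, the Monte Carlo agreement validates the
closed form against its own idealization, not against real membranes with
bonded, crimped, multi-layer networks.

## Curve analysis

Descriptor definitions (the reference study does not state its own):

- **Elastic modulus** — least-squares slope over the first 40 % of the
  pre-yield strain range (configurable), with a provisional yield location
  from a two-segment fit.
- **Yield point** — default `auto`: the knee of a continuous two-segment
  least-squares fit when that fit is essentially exact (relative RMS
  residual < 10⁻⁴ of the stress scale, i.e. noiseless bilinear data),
  otherwise the 0.2 %-offset construction, falling back to the two-segment
  knee when the offset line never crosses the record. The method actually
  used is reported in a `yield_method` tag. The offset construction cannot
  return the knee of a sharply bilinear record exactly (on the study-scale
  bilinear curve it lands ~4 % high in strain), which is why near-bilinear
  data routes to the knee.
- **Post-yield slope** — least-squares slope between yield and break.
- **Break point** — last recorded point (engineering convention).
- **Replicate tables** — population standard deviation for CV (divide by
  n), the common materials-testing convention.

A record that never departs from one straight line has no yield point; its
yield fields are NaN and it is flagged `linear` rather than guessed at.

## Problem sizes and tolerances

Closed-form identities are tested to 10⁻¹²–10⁻¹⁰ relative; quadrature uses
adaptive Gauss–Kronrod at 10⁻¹³ tolerance. Monte Carlo comparisons use 50
seeds × 10⁵ fibers (3-standard-error bands); FOD calibration 100 seeds ×
500 fibers; diameter recovery 400 fibers over ~134 frames. These sizes were
chosen as the smallest at which the statistical bands are meaningfully
tight; all scale linearly if enlarged.

## Known limitations

- The model has no fiber-fiber mechanics: predictions are upper bounds in
  the sense that bonding, crimp and entanglement in real mats dissipate
  load paths the model credits to fibers directly.
- The inverse map is exact only under the uniform-FOD assumption; mats with
  preferential alignment need a different orientation average.
- `ν_xy` enters as measured input (profile or constant); the package does
  not predict transverse contraction.
- The FOD estimator reports axis orientation only; it cannot separate
  overlapping layers and its effective-sample-size default overstates
  independence for long straight fibers (see above).
- Diameter measurement needs ≥ 3 px per fiber and degrades on heavily
  overlapped fields; the per-fragment sampler retains a ~1–2 % negative
  bias there.
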