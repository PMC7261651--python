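# Methods

## Cross-section model

Two parametric cross-sections are supported. A rectangle is width *b*
(lateral) by thickness *h* (depth); a T-beam is a planar rectangle with a
centred trapezoidal fin beneath it, the fin described by its depth and its
widths at the junction and at the free tip ("tapering 16 → 2 µm" means the
wide base sits at the junction). The section plane uses *x* lateral and
*y* positive downward (into the tissue), origin at the top-left corner of
the planar portion; every module shares this convention. All internal
lengths are micrometres — the only unit conversions happen in the buckling
formula and at file boundaries.

Closed forms: rectangle *I* = *bh*³/12; the T-beam uses composite-beam
theory (own-axis moments of rectangle and trapezoid plus parallel-axis
terms about the area-weighted centroid, trapezoid own-axis moment
*h*³(*a*² + 4*ac* + *c*²)/36(*a* + *c*)). Every closed form is checked
against an independent polygon-integration oracle: exact shoelace-type
vertex sums for area, centroid and second moment, orientation- and
translation-invariant. Contours are stored as implicitly closed vertex
lists (first vertex not repeated); an explicitly repeated closing vertex is
accepted and dropped on input.

The "equivalent silicon thickness" helper inverts *EI* = *Ebh*³/12. With
standard composite-beam *I* and E(Si⟨110⟩) = 169 GPa, the study's T-beam is
equivalent to a ≈38.4 µm silicon rectangle. Sizing conventions for
trapezoidal T-beams differ between sources (a commonly quoted matched
thickness is 34 µm); rather than bake in one convention, both the modulus
and the moment formula are exposed, and the 65 × 34 µm rectangle is kept as
the study's named comparison geometry. Silicon's modulus is configurable —
169 GPa is a default, not a constant of the model.

## Buckling

Euler's column formula *P*<sub>cr</sub> = π²*EI*/(*KL*)², evaluated in
GPa·µm⁴/µm² which is exactly mN. *K* is stored with a named boundary
condition and never defaulted silently, because the boundary condition is
the least certain and most consequential input: fixed-pinned (*K* = 0.699)
describes a sharp tip pinned in stationary tissue, fixed-guided (*K* = 1) a
pinned tip in moving tissue, fixed-free (*K* = 2) a tip slipping on a
curved or steeply angled surface. The load ratio between the best and worst
case is (2/0.699)² ≈ 8.19, the "design ~8× stiffer for peripheral targets"
rule; a helper applies it as a required-load multiplier. The thickness
design-space sweep covers the fabricable 5–52 µm range; at 65 µm width,
1.5 mm length and fixed-pinned conditions the silicon rectangle family
spans ~1 mN to ~1.16 N (the 50 µm point is ~1.03 N).

## Vascular damage Monte Carlo

Insertion is assumed vertical and straight, so a probe's damage footprint
is its cross-section contour and the 3-D vessel network can be collapsed by
orthographic projection along the insertion axis (default *z*, the dataset
depth axis; configurable since anatomical orientation of a given dataset
varies). Segments parallel to the axis project to points; they are retained
and flagged rather than dropped.

Each trial places the contour at a uniform random position with a uniform
random rotation about its own centroid (rotation about the centroid makes
the placement distribution independent of vertex-origin choices). By
default placement positions are restricted to the network's projected
bounding box shrunk by the footprint's circumscribed radius, so the rotated
footprint never leaves the data; an `unclipped` mode removes the shrink for
sensitivity checks. Per-trial transection counts over 1000 placements are
summarised by sample mean and sample standard deviation (ddof = 1) — the
Gaussian maximum-likelihood estimates up to the *n*/(*n* − 1) convention,
which we adopt; a histogram curve-fit variant is available alongside. The
count distribution is discrete, so "Gaussian" is a descriptive summary,
never an asserted distributional property.

Because "the device crossed the entire width of a segment" admits two
readings, both are implemented and reported:

- **centerline** — damaged iff the projected centreline has positive-length
  overlap with the footprint interior. A tangency along the boundary is not
  damage (open-interior test), so counts are stable under measure-zero
  perturbations.
- **full-width** — damaged iff the footprint covers a full transversal
  chord of the segment's diameter-wide band (flat-capped). Computed exactly
  by projecting the uncovered part of the band onto the centreline axis and
  looking for a gap in the interval union; covering a segment end also
  severs it. Degenerate (point) projections use disc coverage.

The full-width criterion penalises thin features: the T-beam's 2–16 µm fin
rarely severs a vessel wider than itself, so full-width mode yields a
larger relative advantage for the T-beam than centreline mode. When the two
criteria disagree by more than 5 percentage points, the analysis driver
says so and both are quoted.

Counting runs either as all-pairs brute force or through a shapely STRtree
spatial index with exact predicate confirmation; the two routes are
required to agree exactly in tests. Determinism: one named
`numpy.random.Generator` per run, seed recorded in every result object.

In centreline mode the model admits an integral-geometry cross-check: for
a convex footprint with area *A* and perimeter *P* over an isotropic
stationary segment process of areal midpoint intensity λ and mean projected
length ℓ̄, the expected count is λ(*A* + ℓ̄*P*/π). The test suite verifies
the simulated mean against this closed form within three standard errors,
averaging over independent network replicates so that network-sampling
variance is included in the error estimate.

## Synthetic vascular networks

The generator emulates exactly the statistical structure the damage model
assumes: segment midpoints homogeneously Poisson in a box, orientations
isotropic on the sphere (uniform azimuth, uniform polar cosine), lengths
and diameters i.i.d. The segment count is Poisson with mean
ρ*V*/E[length], making the expected total vessel length equal the
configured length density ρ times the box volume. Defaults: 500³ µm³ box,
ρ = 1.0 × 10⁻⁴ µm/µm³, lognormal lengths (median 60 µm) and diameters
(median 6 µm). The log-space spreads (0.6 for lengths, 0.4 for diameters)
are chosen once as realistic cortical heterogeneity. Sticks whose midpoints
lie near the box face poke beyond it; the generation domain is therefore
carried separately from the tight bounding box and used as the reference
volume for density statistics.

What the synthetic network does *not* emulate: branching topology and
connectedness, spatial correlation between vessels (real capillary beds
are more regular than Poisson), depth-dependent density, the
arteriole/capillary/venule diameter mixture, and vessel curvature. Tests
passing on synthetic networks therefore validate the counting machinery and
its statistical behaviour, not anatomical damage magnitudes. Exact
reproduction of the published per-insertion means (≈6.23 vs ≈9.84 for the
T-beam vs the 65 × 34 µm rectangle) requires the published rat cortical
network itself, read from `data/brain99.txt` when present; its reader takes
a declarative column map (counts-then-records blocks of segment and node
lines) so that format drift produces loud parse errors naming the offending
line, not silent coordinate corruption. Whether boundary-clipped segments
should count as whole segments is unknowable from summary statistics alone;
the package counts every stored segment once and leaves clipping policy to
the network file.

## Kinematics

position(t) = *vt* + (*A*<sub>pp</sub>/2)·sin(2π*ft*), with velocity and
acceleration its exact derivatives; peaks *v* + π*f·A*<sub>pp</sub> and
(2π*f*)²·*A*<sub>pp</sub>/2. Amplitude is stored peak-to-peak because
actuators are specified that way; the phase origin (sine, zero at *t* = 0)
is irrelevant to peaks and documented for plotting. A 70 µm PP default
ceiling mirrors the piezo hardware modelled and is overridable.

## Noise floor and SNR

Vrms is the RMS of five non-overlapping 100 ms snippets concatenated into
one 500 ms block; snippet selection is the caller's job (matching manual
selection practice), with `flag_artifacts` offering a 5σ robust-MAD
threshold and rail detector to help. Window count and length are validated
to one sample of slack. Unit SNR = Vpp/(3·Vrms), scale-equivariant by
construction. Re-referencing, filtering and spike sorting are upstream of
this module.

## Problem sizes and numerical choices

Defaults follow the study conditions: 1000 Monte Carlo trials per geometry,
1.5 mm shank length, 65 µm device width. Statistical tests use fixed seeds
and three-standard-error bands; property tests over random sections use
1000 draws with a 0.1% relative tolerance between closed forms and the
polygon oracle. Geometric predicates use an absolute tolerance of 10⁻⁹ µm²
(length²) to keep measure-zero contacts out of the counts. The
integral-geometry check uses 40 network replicates × 40 placements, enough
for a ~1% standard error on the mean while keeping the whole suite in a few
seconds.
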