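# Methods notes

This note records the models, parameter choices and numerical decisions
behind `iseikit`, and what the synthetic validation does and does not show.

## Problem setting

A fertilized insect egg imaged as a confocal z-stack contains one labeled
sperm flagellum (a tube-like intensity ridge tracing a 3D space curve,
possibly passing over itself), one or two pronuclei and a polar-body
cluster (bright blobs). The measurement chain reduces these to a per-egg
record: five shape descriptors of the flagellum curve at every stage, two
positional descriptors at the pronuclear stage only, plus torsion and
writhe as auxiliary outputs.

Axis conventions: arrays are (z, y, x) with z the slice index; physical
coordinates are (x, y, z) in mm; voxel centers sit at
(index + 0.5) × spacing. One deliberate exception: the *index-unit*
landmark center averages raw integer indices (so two voxels at [3,9,7] and
[5,3,7] give exactly [4,6,7]); the mm-unit center used downstream applies
the half-voxel convention.

## Masking and landmarks

Interactive threshold painting is formalized as (seed voxels + inclusive
intensity range): the mask is the union of connected components of the
in-range voxel set containing a seed. Connectivity defaults to 26 (the
permissive choice matching a painting tool's behaviour; 6/18 available).
The intensity range is always explicit configuration — there is no
universal threshold for immunofluorescence data. Landmark centers are
arithmetic means of masked voxel coordinates; multiple polar bodies are
masked and averaged as one structure, since they migrate to a common
position.

## Centerline tracer

The tracer follows the intensity ridge of the flagellum mask:

- **Density score**: score(v) = Σ 1/(1 + |u − v|) over masked neighbors u
  within the density radius (default 2× the coarsest voxel pitch).
  Distances are in mm, so the score is close to a neighbor count; voxels
  deep inside the tube score highest.
- **Seeding**: point 0 is the score-weighted centroid of the neighborhood
  of the best-scoring voxel; point 1 maximizes score × triangular distance
  kernel peaked at the preferred step s₀ (default 3× the coarsest pitch).
  Ties break to the lexicographically smallest voxel index.
- **Stepping**: candidates must lie strictly ahead of the current direction
  and inside a forward cone (default half-angle 80°; a full half-space
  would re-admit the perpendicular branch at a self-crossing). The
  preferred step shrinks linearly with the candidate's angle off-axis,
  s(θ) = s₀(1 − g·θ/π) with gain g = 0.5, so the tracer takes shorter steps
  into turns. The candidate weight is score × triangular kernel around
  s(θ) × a linear alignment taper (1 − θ/cone). The functional forms
  (inverse-distance density, triangular kernel, linear tapers) are the
  simplest monotone choices for the stated ingredients — neighbor count and
  distance, distance-and-intensity weighting, angle-modified step — and all
  are exposed in `TraceParams`. The soft alignment taper is what makes the
  straight continuation beat an oblique branch of equal density at the
  *first* passage through a crossing, where nothing has been consumed yet.
- **Consumption**: after each step, voxels within the consumption radius ρ
  of the segment between the previous and the new point are removed from
  candidacy and from centroid neighborhoods (only voxels *between* the
  points: the tube around the new endpoint is spared until the next step).
  ρ defaults to a tube-radius estimate sqrt(V/(πL)) from the mask volume
  and a pilot trace. This rule is load-bearing at self-crossings: with it
  disabled, the tracer re-enters the already-traced branch and cycles the
  figure-8 fixture indefinitely (caught by a step budget of one point per
  mask voxel).
- **Bidirectionality**: the trace is repeated from the seed pair in the
  opposite order on a fresh consumption state (seeded with the other
  direction's first segment so it cannot re-trace it), and the halves are
  stitched and resampled at uniform spacing (default 0.002 mm, matching the
  canonical z-step, for cross-sample consistency).

Termination (no candidate, or step below ε = 0.5× the coarsest pitch) is a
normal end-of-tube outcome.

## Descriptors

Differential quantities need up to third derivatives; raw finite
differences on digitized points amplify jitter with each derivative order.
All profiles are therefore evaluated on a parametric smoothing spline
(quintic where the point count allows, so r‴ is continuous). The default
smoothing bound is n·σ̂² with σ̂² estimated from second differences of the
input — the expected residual under i.i.d. point noise; σ̂ = 0 (exact
points) selects exact interpolation through a banded collocation solve
rather than the FITPACK smoothing path, which preserves degenerate inputs
(collinear points) to machine precision. Smoothing is overridable
everywhere. A generalized-cross-validation selector was considered and
rejected in favour of this closed-form noise estimate: it is deterministic,
cheap, and behaves identically across the descriptor suite.

Definitional choices:

- **Net length** is the end-to-end 3D Euclidean distance. This is the only
  reading under which a straight curve has aspect ratio exactly 1 and a
  wavy one a larger value, both of which the definitions require.
- **Total curvature** is ∫κ ds in radians, making
  average curvature = total curvature / arc length exact by construction.
  (Some presentations label total curvature 1/mm; the identity above fixes
  the radian convention here.)
- **Torsion** is undefined where κ vanishes; samples with κ below 1e-6 /mm
  are masked and excluded from the arc-length-weighted average, so straight
  stretches cannot poison it. Sign: positive = right-handed.
- **Writhe** uses the open-curve Gauss double integral evaluated as a
  pairwise sum over uniformly resampled segments (midpoint tangents;
  diagonal and adjacent pairs dropped as singular; 256 segments by
  default). The sum is exactly antisymmetric under reflection and vanishes
  identically for planar curves; convergence is checked against a 4×
  resolution brute-force double loop.
- **Closed curves** (net length ≤ 1e-9 × arc length) make aspect ratio
  undefined and raise rather than returning infinity.

The noise-sensitivity comparison (torsion and writhe vs. curvature) is run
at smoothing 0 — the interpolating fit — because that is the regime that
exposes each estimator's intrinsic error amplification; with smoothing the
ordering's margin only depends on a tuning constant. Under half-voxel
jitter the coefficients of variation order as
CV(τ) ≫ CV(Wr) > CV(κ̄), which is why comparative analyses use the
curvature- and length-based descriptors.

## Synthetic scenes

The generator emulates what matters to the chain and nothing more:

- Egg = ellipsoid with semi-axes (0.40, 0.15, 0.15) mm — plausible for an
  *obscura*-group egg; configuration, not a biological claim. Flagellum
  length defaults to ≈0.3 mm (a "short-sperm" clade value, same caveat).
- Voxel spacing (z, y, x) = (0.002, 0.0005, 0.0005) mm: the canonical
  2 µm z-step with finer xy, reflecting confocal anisotropy.
- Tube intensity is Gaussian in distance-to-curve (σ = tube radius / 2,
  tube radius 0.002 mm ≥ the coarsest pitch so the tube is resolvable);
  blobs are Gaussian spheres. Background 100, tube peak 1000, blob peak
  800 counts; additive Gaussian noise σ = 100 (10% of tube peak) by
  default, Poisson optional and off. Only the bounding box of the
  structures is rasterized; the origin records its placement.
- The figure-8 family crosses itself once with the crossing offset out of
  plane by less than a tube diameter (default 0.0015 mm), so the true curve
  never self-intersects while its voxel tube does — exactly the case the
  consumption rule exists for.
- Ground-truth descriptors are closed-form for line / circle-arc / helix
  and high-resolution quadrature on exact derivatives otherwise (flagged
  `numerical`; doubling the quadrature grid moves them by <0.5%).
- Cohorts: an `EffectModel` maps stage or cross to multiplicative shifts of
  curve parameters, with between-egg log-normal variability (default CV
  5%, a typical biological between-individual scale). The same seeded
  generator drives both rasterized datasets and fast descriptor-level
  cohorts (no rasterization) for calibration studies.

What passing synthetic tests does *not* show: robustness to optical PSF
anisotropy and depth attenuation, chorion autofluorescence, antibody
background, touching structures, or stage miscalling — real stacks add all
of these, and the masking range/seed configuration absorbs them only
partly.

## Statistics

One-way ANOVAs use the classical between/within decomposition; two-way
ANOVAs use sequential (Type I) sums of squares in the fixed order female,
male, female × male, each tested against the residual mean square. The
sequential choice matches the base-R default that this style of unbalanced
cross design is normally analyzed with; on unbalanced data Type II/III
would give different main-effect F values, so the choice is explicit and
configurable in spirit (the decomposition order is fixed by the reported
effect order). Tukey HSD uses the Tukey–Kramer standard error for unequal
n and studentized-range p-values; post hoc tables are produced only for
one-way results significant at α = 0.05. No multiple-testing correction is
applied across descriptors (deliberately preserved from the original
workflow). Degenerate inputs (zero within-group variance) are reported as
F = 0 / p = 1 when all values are identical, or F = ∞ with a
machine-minimum p and an explanatory flag otherwise, never as NaN.

The type-I calibration of the full comparison pipeline runs 200 null
cohorts of 4 stages × 6 eggs at descriptor level (no rasterization) and
checks the rejection count of a pre-chosen descriptor row against the
central 99% binomial band — problem sizes chosen to make the whole
validation suite convenient to run routinely.

## Known limitations

- The tracer's weighting formulas are reconstructions: the original
  interactive tool's exact kernels and cone are not recoverable, so the
  simplest monotone forms are used and exposed as parameters.
- Consumption removes voxels in a tube around each new segment (the
  literal "between the points" reading); a sphere-at-endpoint variant
  would behave differently at very tight turns.
- Landmark seeds must be supplied (config, or ground truth in synthetic
  runs); there is deliberately no automatic blob detection.
- Writhe is reported for open curves; it is a geometric helicity measure
  here, not a topological invariant, and has no twist/linking
  decomposition without a ribbon framing.
- Torsion of near-straight sperm is intrinsically ill-posed; records where
  most of the curve falls below the curvature floor report NaN.
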