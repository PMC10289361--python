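# Methods

## The measurement problem

A urolith imaged in CT appears as a dense object (several hundred to more
than 1000 HU) against a near-water background. Its clinically relevant
size — volume and maximum diameter — must be read off a voxelized,
blurred, noisy image. Two effects dominate the error budget: the surface
partial-volume effect (boundary voxels contain a mixture of stone and
surroundings, so their HU lies between the stone and background values)
and the scanner's point-spread blur, which widens that mixed shell. The
package implements four semi-automated segmentations that differ in how
they place the threshold inside the mixed shell and whether they correct
the volume for it afterwards, plus the optimization and agreement
machinery needed to compare them against an independent reference.

## Segmentation model

Processing is restricted to a spherical annotation per stone (centre +
radius guaranteed to contain the stone). A voxel belongs to the region of
interest iff its centre lies within the radius; thresholding is inclusive
(HU ≥ t). The working threshold is either a global constant P1 (`abs*`)
or P1 × median HU of a rough 20 HU segmentation of the same stone
(`med*`); the rough threshold is a named, configurable constant. After
thresholding, the 26-connected component containing the annotation centre
is selected (if the centre voxel is below threshold: the nearest
component, ties to the largest then lowest linear index), then interior
cavities are filled in 3D (background = regions connected to the crop
border, 6-connectivity). The surface factor P2 never modifies the mask:
it acts only in the volume formula. These connectivity and tie-break
choices are conventions, not physics: 26-connectivity is the most
permissive way to keep a stone intact, 6-connectivity gives the standard
surface shell, and the component/fill order (select, then fill) is fixed
and tested.

## Morphometry

Volume: `V = (N − P2·N_surf) · dx·dy·dz`, reported in mL. `N_surf`
counts mask voxels with at least one 6-face neighbour (or the grid
boundary) outside the mask. V is linear and strictly decreasing in P2
whenever a surface exists; since `N_surf ≤ N` and P2 < 1 the corrected
volume stays positive.

Diameter: the maximum Euclidean distance between surface-voxel centres
plus one voxel edge to account for the half-voxel extent beyond each
centre (0.7 mm on the default grid; for anisotropic grids the edge along
the dominant axis of the maximizing pair, a generalization that reduces
to the single edge in the isotropic case). The search runs on surface
voxels only, with a convex-hull prefilter above 400 points. Both
restrictions are lossless — the farthest pair of a finite point set is
attained at hull vertices, which are surface voxels (a voxel with all six
face neighbours present is a midpoint of its axis neighbours, hence not a
vertex) — and the tests assert exact equality with the naive
all-voxel-pairs scan. On isotropic grids squared distances are exact
integers times the squared spacing, so the maximum is bit-reproducible.

An optional `pv_affects_diameter` switch (off by default) additionally
shrinks the diameter by P2 × one voxel edge. It exists because the
surface correction's scope is ambiguous in principle — a fractional
factor cannot remove whole voxels geometrically, so the volume-only
interpretation is the default.

## Parameter optimization and validation

Cost over a stone set: `Σ_stones w_V·|Ve − Vr| + w_D·|De − Dr|` with
weights (4 /mL, 1 /mm). Vr, Dr are the 3-rater means. The optimizer is an
exhaustive coarse grid — 2 HU steps on [50, 1000] for absolute
thresholds, 0.005 steps on (0, 1] for median fractions, 0.01 steps on
[0, 0.9] for P2 — followed by a deterministic fine grid (an eighth of a
coarse step, within one coarse step of the coarse argmin). A line-search
refinement such as golden section is deliberately not used: the cost is a
noisy step function of the threshold (it changes only where a voxel's HU
crosses the candidate value), so unimodality cannot be assumed below the
grid scale; a fine sub-grid is deterministic and honest about that
structure. Ties on flat cost regions resolve to the smallest P1, then the
smallest P2. Parameter settings that leave a training stone unsegmented
incur a large finite penalty (1e6 per stone) rather than an error, so the
search continues past infeasible regions.

Validation repeats R times: split the stones at random into train
(default 80) and validation (default 21) sets, optimize on train,
evaluate on validation the ICC, mean and SD of `reference − estimate`
(this sign convention is fixed everywhere), then aggregate mean and SD of
parameters and metrics over repetitions. Each repetition's RNG stream
derives from (master seed, repetition index), so any single repetition
can be recomputed in isolation and results are independent of execution
order. Segmentation results are memoized per (stone, threshold); the
cache is semantically invisible (tested against the uncached public
pipeline). A validation stone left empty at the chosen parameters is
recorded as volume 0 / diameter 0 — a method failure, not a crash — and
does not occur at the optima under the default conditions.

## Agreement statistics

ICC variant: ICC(A,1) — two-way random effects, absolute agreement,
single measurement — treating {estimate, reference} as two raters,
computed from the standard mean-squares decomposition. Absolute agreement
is the conservative choice for method-versus-reference comparison because
it penalizes systematic bias as well as scatter; ICC(C,1) is available
via the `variant` argument, and Pearson r is reported alongside.
Bland-Altman limits are mean ± 1.96 SD of the paired differences (n−1
denominator throughout). Variance homogeneity across methods uses the
classical univariate Bartlett chi-square test applied separately to the
volume differences and the diameter differences, matching the two
p-values the experiment reports; a joint covariance-equality test (Box's
M) is intentionally out of scope.

## The phantom simulator

What it emulates: water background (0 HU), stones of constant interior
density placed on a mutually separated jittered lattice (annotation
spheres provably disjoint), 0.7 mm isotropic voxels, surface partial
volume via supersampled sub-voxel sampling (default 8³ sub-points per
boundary voxel; interior/exterior voxels are classified exactly via a
conservative Lipschitz bound on the implicit shape function, verified
against full supersampling), scanner blur as an isotropic Gaussian PSF
(default σ 0.5 mm, a standard surrogate when only the reconstruction
kernel is known), additive Gaussian HU noise (default SD 10, a low-dose
order of magnitude; truncated at ±5 SD so rendered HU provably stays
within [background, density] ± 5 SD), and three raters per stone drawing
`truth · (1 + cv·z)` (default cv 3%, clipped positive — multiplicative
because caliper and water-displacement errors scale with magnitude).

Shapes are star-convex: ellipsoids optionally modulated by a bounded
low-order quadratic-harmonic radial perturbation (total relative
amplitude < 0.5, keeping star-convexity). Ground truth volume is closed
form for spheres/ellipsoids and a dense spherical quadrature
`V = (4π/3N) Σ r(u_i)³` (N = 16384 Fibonacci directions) for perturbed
shapes — effectively exact for these smooth radii and verified against
16× supersampled rasterization within 1%. Ground truth diameter is twice
the largest semi-axis for the symmetric families and the maximum pairwise
distance over 8192 surface samples (hull-pruned) for perturbed shapes.

Stone population defaults, chosen once to emulate a mixed clinical
collection including large animal stones: maximum diameter log-uniform on
5–30 mm (smallest stones just under 5 mm; between-stone volume SD ≈ 2 mL,
the spread at which reported agreement levels of ICC ≈ 0.99 with ~0.2 mL
difference SDs are meaningful), axis ratios uniform on 0.55–1 subject to
the 4 mm minimum-diameter inclusion rule, density uniform on 300–1500 HU.

What it does not emulate: anatomy (vertebrae, soft tissue), beam
hardening and streaks, kernel-specific noise texture, internal density
gradients within a stone, and any rater bias structure beyond unbiased
multiplicative noise. Passing tests therefore demonstrate correctness of
the algorithms and the internal consistency of the experiment under this
forward model, not clinical performance on patient scans.

### Sensitivity to density homogeneity

One forward-model property deserves emphasis. With the default density
spread (300–1500 HU), a single fixed threshold cannot sit at half-maximum
for every stone: it lies below half-maximum for dense stones (systematic
oversegmentation of the blurred shell) and near or above it for light
stones (undersegmentation). The fixed-threshold methods consequently
carry roughly 4× the error variance of the adaptive median-based methods,
and Bartlett's test detects the difference decisively at n = 101. When
the stone population has relatively homogeneous contrast — e.g.
`PhantomConfig(density_range_hu=(600, 1200))` — all four methods perform
near-identically (volume ICC ≈ 0.998, Bartlett p ≈ 0.9 for both
quantities): the equivalence of fixed and adaptive thresholding is
contingent on density homogeneity of the collection, which is worth
checking before transferring a fixed threshold across stone populations
of heterogeneous composition.

## Numerical choices and degenerate inputs

- All randomness flows through one master `SeedSequence` with documented
  children (shape sampling, scan noise, raters, placement; split RNG per
  repetition). Identical seeds give bit-identical phantoms.
- Thresholds are memoized at 1e-6 HU resolution; cost grids are float64.
- Empty ROI, empty segmentation, empty mask, degenerate PV correction,
  zero-variance ICC/Bartlett inputs and mismatched stone ids each raise a
  dedicated exception (see `lithoseg.errors`).
- A single-voxel mask has diameter 0 + one voxel edge; for anisotropic
  spacing the largest edge is used in that degenerate case.
- CSV round trips use `%.17g` formatting and round-trip float parsing, so
  written references reload bit-exactly; NIfTI volumes round-trip with
  spacing preserved to 1e-6 mm.

## Problem sizes

The shipped experiment uses 101 stones with 100 repetitions of the 80/21
split protocol (the package supports arbitrary repetition counts; report
stds are the across-repetition spreads at the stated count). The test
suite exercises smaller phantoms (6–24 stones) for unit and property
checks and the full 101-stone protocol for the end-to-end checks.
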