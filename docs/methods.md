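# Methods

## Kinematic model and angle conventions

The body frame is built per frame from three thorax points: the
longitudinal axis x runs from the first to the second point, the
dorsoventral axis z is the thorax-triangle normal, and y = z × x. The
construction is equivariant, so every downstream quantity is invariant to
rigid motion of the whole scene; this is also why all deformation
measurements are taken in body coordinates.

Wing posture is parameterized against a **stroke plane** whose inclination
γ from horizontal defines the basis: normal n = (sin γ, 0, cos γ) in body
coordinates, lateral in-plane axis s2 (projection of body-y), and
s1 = s2 × n. The three angles are

* flapping φ = azimuth of the base-to-tip unit vector d projected into the
  plane, `φ = atan2(d·s1, d·s2)`;
* deviation θ = elevation out of the plane, `θ = asin(d·n)`;
* incidence α = rotation of the chord direction (recovered from the
  marginal-joint landmark) about d, measured from the in-plane reference
  `u0 = (n × d)/|n × d|`.

This is a standard insect-flight convention; the exact Euler sequence used
by earlier hardware pipelines is not re-derivable from published summaries,
so the convention above is a documented package choice used consistently by
both the generator and the estimator.

The stroke plane is estimated by total least squares (smallest principal
axis of the mean-centred tip path), per cycle and averaged for the reported
angle, or supplied explicitly. When deviation is nonzero the tip path is
not exactly planar, so the TLS plane differs slightly from the commanded
plane of a synthetic recording; exact angle round trips therefore either
use zero deviation or pass the commanded inclination. Reversal detection
uses sign changes of the centred-difference angular velocity with
parabolic (three-point) sub-frame refinement, giving frequency resolution
well below one frame interval. Smoothing is off by default so that tests
are exact; a moving-average window can be configured.

## Deformation measurement

The leading-edge landmarks wb, mj, wt define the rigid wing plane each
frame. Deflection of a trailing-edge landmark is its signed perpendicular
distance to that plane divided by wing length R. The sign convention
follows the free-flight observation that the trailing edge bows **toward
the instantaneous motion direction** (the pressure side): the plane normal
is oriented by the central-difference velocity of the trailing-edge
centroid, and frozen from the previous frame when the wing speed drops
below 1e-6·R per frame (stroke reversals), where the deflection itself
vanishes.

**Mid-stroke** is defined as the crossing of the flapping angle through the
midpoint of the two reversal extremes bounding a half-stroke — well defined
for non-sinusoidal strokes, unlike the peak-velocity alternative — with
linear interpolation in time and averaging across cycles. Downstroke is
the half-stroke with increasing flapping angle (sweep toward the
forward-inclined in-plane axis). The spanwise deflection profile through
the four landmark values uses PCHIP interpolation (monotone-preserving,
exact at the landmarks, reproduces linear data).

The allometric fit `β = a Fv^b` is ordinary least squares on
log-transformed data; the 95% CI on b is t-based (the original analysis
does not state its CI construction). The chord-corrected stiffness proxy
is the exact arithmetic `l³/β`.

## Static bending

`EI = F l³/(k β)` inverts the end-loaded uniform-cantilever relation; k
defaults to 3 but is exposed because real wings are non-uniform beams. Load
distances l are supplied per measurement point rather than hard-coded
(published geometry fixes only one point, at 0.42 of wing length). For the
WBLE condition the cantilever span is interpreted as the chord-wise
distance from the leading-edge support line. Forces below a configurable
load-cell floor (default 1e-6 N) are flagged, never dropped. Group
comparisons use a two-sided permutation test on the mean difference with
the add-one correction `p = (1 + #{|perm| ≥ |obs|})/(1 + n_perm)` — a
distribution-free stand-in; the classical repeated-measures test family is
deliberately out of scope.

## Morphometrics

GPA is the full iterative variant: centre, scale to unit centroid size,
rotate (SVD with the determinant constrained positive, so reflections are
never introduced) to the evolving mean, iterated to 1e-10. Because the
converged orientation would otherwise inherit the arbitrary orientation of
the first configuration, the output is rotated to a canonical frame (mean
shape's principal axes on the coordinate axes, sign fixed by the
largest-|x| landmark); this makes the alignment invariant to per-specimen
similarity transforms of the input, which is also the key testable
property. PCA is on covariance (coordinates share units after scaling),
without tangent-space projection by default (negligible for small shape
variation; a config flag enables it). Eigenvector signs are fixed by
making each vector's largest-magnitude element positive. Per-landmark
contributions of a component are the squared x+y loadings normalized to
100%. When all specimens are identical, eigenvalues are returned as zeros
(and percent variance as zeros) rather than raising, mirroring the
constant-data behaviour of the phylogenetic decomposition.

TPS uses the kernel U(r) = r² log r with U(0) = 0 and affine side
conditions; bending energy is tr(W'KW), zero exactly for affine maps, and
invariant to rigid motions applied jointly to source and target.

## Phylogenetic PCA

The BM covariance C is computed by node depths (root depth 0); any input
newick is rooted at its seed node. Inversion is Cholesky-backed; a singular
C (duplicate tips, zero branches) raises with a repair hint instead of
silently pseudo-inverting. Covariance mode and untransformed projection of
GLS-centred data follow the convention of the widely used R
implementation; on a star phylogeny with equal branch lengths the result
reduces exactly to ordinary PCA — the module's primary oracle. Species
means are arithmetic means of GPA-aligned coordinates, sorted by label for
determinism.

## Wing planform

Area comes from the polygon (shoelace, via shapely), span from the extent
of projections on the span axis (the base-to-tip definition; the maximal
perpendicular extent is an untestable alternative from published
summaries). Chords are polygon–line intersection lengths; the second
moment uses midpoint-rule strip integration (500 strips by default, giving
relative errors ~1/(4n²) ≈ 1e-6 on smooth outlines, far inside the 0.1%
closed-form checks). Both the dimensional S₂ and the non-dimensional r̂₂
are available, sidestepping normalization-convention ambiguity.

## Synthetic data: what it emulates and what it does not

`simulate_flight` drives the leading edge rigidly with φ = (Φ/2)·sin(ωt),
θ = θ_A·sin(2ωt) (a figure-eight deviation), and a smooth incidence
profile; trailing-edge landmarks are additionally displaced along the
wing-plane normal by amplitude·|cos(ωt)| — peaking at mid-stroke,
vanishing at reversals — signed toward the motion direction. Landmark
layout (marginal joint at 55% span, 20% chord; vein tips from RP at
(0.85, 0.22) to AA at (0.25, 0.35)) approximates a scarab hindwing.
Defaults are the measured study conditions: 118 Hz (109 Hz for the second
species), 120° stroke amplitude, 34° stroke plane, 20 mm wing, 0.5 g body,
CuA the most-deflecting landmark at 0.12·R. Isotropic Gaussian noise (mm,
per coordinate, applied last) emulates digitization error; its magnitude is
a free parameter since no published value exists, and 0.05 mm is used in
noise studies. The generator does **not** model aerodynamic forces, wing
camber between landmarks, body rotation, or tracking dropouts — passing
round trips demonstrate estimator correctness under the stated geometry,
not robustness to those real-data effects.

`simulate_shape_radiation` evolves each of the 50 coordinates as
independent BM along the tree (species means), adds clade offsets at named
nodes (inherited by descendants) and per-specimen digitization noise. It
matches the analytic tip covariance σ²C but has no correlated-rate or
selection structure. `simulate_bending` and `simulate_allometry` are exact
closed forms plus multiplicative/log-normal noise.

Every generator consumes one explicit seed and its own RNG stream; outputs
are bit-identical across calls.

## Problem sizes and numerical choices

Simulation studies use desk-scale sizes chosen once: 100 seeds for noise
RMSE studies, 500 replicates for Monte-Carlo covariance and CI-coverage
checks, 50–100 runs for detection-rate properties, 20 species × 3–5
specimens for radiations. Tolerances: exact round trips are asserted at
1e-6 deg (angles), 1e-10 (deflections, GPA distances), 1e-12 (stiffness
inversion); statistical checks use the error bars of their own estimators
(3–4 s.e.). Degenerate inputs (collinear triads, coincident landmarks,
singular C, zero deflection) raise informative errors rather than
returning NaN.

## Known limitations

* Incidence recovery needs the marginal joint off the span axis; a truly
  collinear leading edge only yields flapping and deviation (frames are
  flagged).
* The estimated stroke plane is biased for strongly non-planar tip paths;
  supply the inclination explicitly in that regime.
* Percent-variance figures from ordinary vs phylogenetic PCA are not
  comparable across datasets with different tree depths (eigenvalues scale
  with 1/depth).
* The permutation contrast assumes exchangeability between groups; it is
  plumbing for synthetic comparisons, not a replacement for the matched
  inferential designs used on real specimens.
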