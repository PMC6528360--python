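# Methods

This note documents the models, numerical choices, and limitations behind
`ontomorph`.  It covers what each statistic assumes, which knobs matter,
what the synthetic generator does and does not emulate, and where the
design was genuinely open.

## Superimposition

Shapes are 2D landmark configurations with k ≥ 3 points.  Centroid size is
CS = √Σᵢ‖xᵢ − x̄‖².  GPA is *partial* Procrustes: every configuration is
centred and scaled to unit CS, then rotated to an iteratively re-estimated
consensus by SVD-based least squares with the determinant constrained to
+1 — reflections are never fitted, so all specimens must be digitized on
the same side.  The consensus is the unit-scaled arithmetic mean of the
aligned shapes; iteration stops when its root-mean-square change drops
below `tol` (default 1e-8, `max_iter` 100).

The converged solution is reported in a canonical orientation: the
consensus is rotated onto its principal axes and the residual 180°
ambiguity is resolved by the sign of the third moment of x (falling back
to y).  This makes the output invariant — to ~1e-12 in practice — under
arbitrary similarity transforms applied to any input configuration, which
an align-to-first-specimen convention would not be.  The sign rule is
undefined for shapes whose odd moments all vanish (perfectly symmetric
configurations); biological outlines are never in that class.

All linear statistics operate on chord distances after orthogonal
projection from the pre-shape sphere onto the tangent space at the
consensus (not stereographic projection).  For the shape variation the
package targets (Procrustes distances ≲ 0.3) the projection error is
second-order and immaterial.

## Sliding semilandmarks

Semilandmarks are defined by (before, slider, after) triples.  During
sliding, each semilandmark moves only along the unit chord from its
*before* to its *after* neighbour evaluated on the specimen itself; the
displacement magnitudes jointly solve the exact linear least-squares
problem minimizing the thin-plate-spline bending energy of the specimen
relative to the current consensus.  Because the unslid position is a
feasible point of that quadratic program, bending energy can never
increase within a sliding step; the per-iteration energies are recorded in
`AlignedDataset.bending_energy_trace`.

Sliding is interleaved with superimposition during the first `slide_iter`
(default 5) GPA iterations only, after which plain GPA runs to
convergence.  Sliding at every iteration admits a slow drift mode — the
semilandmarks creep along their chords as the consensus co-adapts — that
stalls the consensus-change criterion without improving the fit; capping
the sliding phase is the standard remedy and changes final coordinates
only at the drift scale.  Bending-energy sliding is the implemented
criterion; minimum-Procrustes-distance sliding is deliberately not offered
because the analysis chain downstream (GI in particular) is built on the
bending-energy geometry.

## Thin-plate spline, principal and partial warps

The bending-energy matrix of a reference uses the kernel U(r) = r² ln r
(not r² ln r²; the two differ by a global factor 2 that cancels in GI
slopes and all relative comparisons).  L = [[K, Q], [Qᵀ, 0]] with
Q = [1 | x | y]; the bending-energy matrix is the upper-left k×k block of
L⁻¹, numerically symmetrized.  It is PSD with exactly three null
directions (the affine functions 1, x, y); coincident reference landmarks
raise an error naming the pair.

Principal warps are the k−3 nonzero-eigenvalue eigenvectors (ascending);
partial-warp scores are per-axis projections of tangent-space deviations
from the consensus.  The uniform component is the 2-dimensional
orthonormal basis obtained from the four affine fields of the consensus
after removing the translation, rotation, and scale fields; because
aligned shapes are centred, optimally rotated, and tangent-projected,
principal warps plus the uniform component reconstruct every shape to
machine precision (asserted at 1e-8).

## Linear models and RRPP

Procrustes ANOVA fits OLS to the n×2k coordinate matrix with sequential
(type-I) sums of squares.  Null distributions use residual randomization:
for each term, residuals of the reduced model (all prior terms) are
permuted across specimens and the term SS recomputed — for nested hat
matrices this reduces to ‖(Hᵢ − Hᵢ₋₁) R_π‖², which is what is computed.
p = (1 + #{null ≥ observed})/(1 + n_perm), so p is never 0 and never below
1/(n_perm+1).  Z effect sizes standardize the observed statistic within
the null on the log-SS scale by default (SS nulls are right-skewed);
`log_z=False` switches to the raw scale.  Size enters allometric models as
ln CS by default — the standard allometry choice, and the same convention
the generator uses, so recovery tests close the loop.

Allometric-slope comparison regresses shape on ln CS within each group and
reports pairwise angles (degrees, in [0°, 180°]; slope vectors are signed)
with RRPP nulls under the common-slope (no interaction) model.  The
statistic permuted is the angle itself.

Default `n_permutations` is 10,000 for production runs; tests and the
acceptance script use 199–999 to stay inside their time budgets — the
choice affects only the resolution of p, not the statistics.

## Trajectory analysis

A group's trajectory is its ordered stage-mean sequence (cell means, which
are the least-squares means of the full factorial).  Attributes:

- **magnitude** — path length, the summed Euclidean distances between
  consecutive stage means;
- **direction** — the leading principal axis of the group's stage means,
  oriented from first toward last stage; angles between groups use the
  absolute-correlation convention (θ ∈ [0°, 90°]) because a principal
  axis has no intrinsic sign;
- **shape** — the stage means treated as an m-point configuration in
  R^2k, centred, scaled to unit size, and rotated by orthogonal Procrustes
  computed in the joint span of the two trajectories (equivalent to the
  full-space solution; reflections permitted since shape-space axis signs
  are arbitrary).  D is the residual Frobenius distance.

Nulls for all three attributes share one permutation stream per seed
(residuals of the additive group + stage model, i.e. the no-interaction
null under which groups share one trajectory up to offset).  Magnitude
differences are reported alongside θ and D as optional output (`dL`
columns).  Calibration note: in regimes with *no* ontogenetic signal at
all, the θ test is mildly anticonservative (~8% empirical size at nominal
5%), because null datasets share the estimated common stage profile while
such observed data share nothing; under the actual null hypothesis of a
common trajectory the size is close to nominal.  Degenerate (zero-length)
trajectories are flagged and their θ/D comparisons reported as undefined.

## Disparity

Procrustes variance of a group is Σ‖yᵢ − ȳ‖²/n (divisor n, following the
trace-of-covariance definition; not n−1).  Pairwise |PV_g − PV_h| are
tested by permuting group-mean-centred residual vectors among specimens
with group sizes fixed.  The grouping key is pluggable (species, stage, or
species×stage), and the pipeline additionally reports two flavours of
inter-specific disparity per stage — pooled-specimen variance and
among-species-mean variance — labelled distinctly, since both readings of
"inter-specific disparity" are in circulation.

## Modularity (CR) and integration (GI)

CR compares squared between-module covariances with the geometric mean of
squared within-module covariances, excluding diagonals *and*
within-landmark x–y blocks (orientation artifacts with no anatomical
meaning; a flag restores them).  The null reassigns whole landmarks (x and
y travel together) to modules of the original sizes; p is the proportion
of the null at or below the observed CR.  For non-modular data the null is
centred on 1.

A caveat that matters for interpretation: Procrustes superimposition
itself induces covariance among all landmarks (centring, scaling, and
rotation each mix coordinates), so data generated with exactly
block-diagonal landmark covariance no longer look block-diagonal *after*
GPA.  CR's own null partly absorbs this, but recovery tests of the "CR → 0
for block-diagonal generation" kind are run on tangent-frame generator
output, where the generating covariance is untouched.

GI regresses ln(partial-warp variance) on ln(bending energy), with
per-warp variance the sum of the x- and y-score variances (isotropic
treatment; per-axis regression is available behind a flag).  The uniform
component is excluded — its bending energy is 0 and its log undefined.
Classification uses a ±0.05 band around −1 for "self-similar"; the band is
an implementation default, configurable, and not an inference about any
particular study's threshold.  Zero-variance warps are dropped with a
warning; the slope is invariant to a global rescaling of bending energies,
so the kernel convention cannot leak into GI.

## Synthetic generator

`generate_dataset` composes, in the tangent space at a fish-like template
(35 landmarks: 15 fixed, 20 semilandmarks on 4 outline curves):

  shape = template + (1 − convergence[stage])·species_offset
        + trajectory_path[species, stage]
        + allometric_vector[species]·ln(CS/CS_ref) + correlated noise,

then applies a random rotation, translation, and scaling to the sampled CS
as the *last* step, so GPA must remove exactly what was added.  Noise is
Gaussian with a landmark-level block-correlation structure (within-module
vs between-module correlation, x and y independent); the implied
covariance is checked for positive semidefiniteness before sampling.
Defaults encode the regime the package is designed to analyse: convergence
of species means peaking at the late-juvenile stage (factor 0.7), adult
divergence vectors orthogonal to the shared ontogeny axis, per-stage noise
SDs (0.006, 0.0045, 0.003, 0.009) giving a U-shaped disparity profile with
the adult maximum, and per-stage CS ranges (20–35, 35–50, 50–65, 90–140 mm)
that are disjoint so centroid-size tertile staging recovers the generating
stages.  `four_species_scenario()` freezes this design at the cell sizes
34/35/37/21, 16/15/17/18, 26/27/29/38, 18/18/19/22 (390 specimens, 291
juveniles + 99 adults).

What the generator does *not* emulate: digitization error structure,
curved (non-piecewise-linear) trajectories, biomechanically realistic
outlines, within-stage age structure, or measurement covariance between x
and y of one landmark.  Passing recovery tests therefore demonstrate that
the estimators recover the generating structure under the stated model,
not that real fish data satisfy that model.

## Staging

Juveniles are binned per species into centroid-size tertiles using
average-rank percentiles (stage 1 ≤ 33⅓, stage 2 ≤ 66⅔, stage 3 above;
adults are stage 4).  Average ranks make ties share a stage and the rule
invariant under monotone rescaling of CS.  Species with fewer than 3
juveniles are staged by the same rule with a warning.

## Determinism and seeding

Every stochastic routine takes an explicit seed and uses an isolated
`numpy` Generator.  The pipeline fans a single global seed into
independent per-step streams by hashing the step name (SHA-256, reduced
mod 2³¹), so toggling one step never perturbs another's permutations;
reruns with the same seed are byte-identical.

## Known limitations

- 2D only; no NTS format; no relative-warp α-weighting.
- Procrustes-distance sliding is not implemented (bending-energy sliding
  only).
- The θ permutation test's mild anticonservativeness in zero-signal
  regimes, above.
- CR is defined for exactly two modules.
- TPS `SCALE` factors are applied when present; whether source
  coordinates were digitized in physical units must be known to the user.
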