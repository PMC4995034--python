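# Methods

This note documents the statistical procedures implemented in `wingmorph`,
the synthetic-data model used to test them, the numerical choices that are
not forced by the mathematics, and what the package's passing tests do and do
not establish about real wing data.

## Shape model and superimposition

A specimen is a configuration of k = 18 (or a declared subset of 5, 7 or 9)
2-D landmarks at wing-vein intersections, in arbitrary but internally
consistent image units. Generalized Procrustes analysis removes translation
(centring), size (scaling to unit centroid size), and orientation (optimal
rotation against the running consensus, reflections disallowed since all
wings are from the same body side). This is a full Procrustes fit, matching
the default behaviour of the standard desktop tools for wing morphometrics.

Convergence is declared when the root-summed-squared change of the consensus
falls below 1e-10 (at most 100 iterations; non-convergence is flagged and
logged, not raised). After convergence the whole solution is rotated once
more so the consensus lies in a canonical orientation — major principal axis
along x, the remaining 180° ambiguity resolved by the sign of the coordinate
third moment. GPA is otherwise only order-invariant up to a global rotation;
the canonical orientation makes the consensus itself independent of specimen
input order, which downstream code and tests rely on.

Shape statistics use tangent-space coordinates: each aligned shape is
orthogonally projected at the consensus (the component along the consensus
vector removed, the consensus added back). For wing-scale variation
(Procrustes distances ≲ 0.1) the linearization error is far below sampling
noise. The tangent covariance has rank at most 2k − 4: two translations, one
rotation and one scaling degree of freedom are consumed by superimposition.

## Allometry

The allometric effect is the percentage of total tangent-space variance
predicted by least-squares regression of every tangent coordinate on log
centroid size,

    percent = 100 · Σ_j SS_pred,j / Σ_j SS_tot,j ,

tested by permuting the size vector against the shapes (default 10,000
randomizations, add-one correction so p ≥ 1/(n_perm + 1), bit-reproducible
given a seed). Natural-log size is the default regressor (a `size_scale`
flag switches to linear); with sizes spanning less than a factor of two the
two choices differ negligibly. The allometric component is deliberately not
removed before classification — size-driven shape change is treated as part
of the identification signal — but `remove_allometry` provides the
residualized alternative.

The plain percent-predicted estimator is inflated under the null by fitting
one regressor to noise: its expectation at true fraction f is approximately
f + (1 − f)/(N − 1) (about 0.3 percentage points at N = 312). Calibration
tests compare replicate means against this analytic expectation rather than
against f itself; the pipeline reports the raw estimator, as the field's
standard software does.

## CVA, Mahalanobis distance, and reclassification

Group-level statistics operate in a principal-component subspace of dimension

    d = min(#components reaching 99% of variance, N − g − 1, rank),

because the pooled within-group covariance of 32 tangent dimensions is
singular or ill-conditioned at per-group sample sizes of 14–30. The 99%
retention default is a declared choice (configurable via
`variance_retained`); the original desktop tools do not document their
internal rule, so no claim is made that this reproduces any particular
program.

Canonical axes solve the generalized eigenproblem B v = λ W v (B: between
means, W: pooled within) and are scaled so pooled within-group variance per
axis is one; axis signs are fixed by making the largest-magnitude loading
positive. Mahalanobis distances between group means use W in the reduced
space via a Cholesky solve; a singular W raises an error that points at the
dimension-reduction knob rather than returning pseudo-inverse guesses.

Leave-one-out reclassification is strict: for every held-out specimen the
PCA reduction, group means and pooled covariance are re-estimated from the
remaining specimens. This is slower than reusing the global subspace but
avoids the optimism of training on the test point. Exact distance ties are
assigned to the first group and logged (a probability-zero event for
continuous data). Note the well-known pessimistic bias of LOO at chance:
removing a specimen shifts its own group's mean away from it, so
identical-distribution accuracies sit at or slightly below 50%.

The pairwise table reports, in cell (i, j), the percent of group-i specimens
correctly assigned in the i-vs-j test; it is genuinely asymmetric. The
summary "mean accuracy" is the unweighted mean over all off-diagonal cells.
The single p-value printed with the species table is a permutation test
(1,000 label permutations) on the mean pairwise Mahalanobis distance — a
distribution-free stand-in for the unstated parametric test such tables are
conventionally annotated with.

The landmark-subset evaluation re-runs GPA and the pairwise table after
restricting to declared 1-based landmark subsets (defaults: the 5-, 7- and
9-landmark sets used for genus discrimination) and reports minimum and mean
off-diagonal accuracy per subset.

## Thin-plate splines

Standard 2-D TPS with kernel U(r) = r² log r²: exact interpolation at
landmarks, affine part separated, bending energy from the quadratic form
w_xᵀ K w_x + w_yᵀ K w_y (clipped at zero against roundoff). Bending energy
is zero iff the target is an affine image of the source and is
direction-dependent in general. Deformation grids are drawn on a 20×20
lattice over the source bounding box padded 10%. Wireframe link topology is
a package-level fixture (`tps_warp.DEFAULT_LINKS`) tracing the template's
outline and interior vein points; it is editable because link choice is
purely presentational. Shapes at canonical-axis extremes come from
regressing tangent coordinates on the axis scores; the intercept is pinned
to the consensus so score 0 maps to the consensus exactly.

## Neighbor-joining tree

Classical Saitou–Nei agglomeration with Q-criterion ties broken toward the
smallest index pair (deterministic), negative branch-length estimates
clamped to zero with the total deficit recorded. On additive matrices the
generating topology and branch lengths are recovered exactly (tested against
a known 5-taxon fixture and the four-point condition).

Bootstrap supports resample specimens with replacement within each taxon and
recompute group means, pooled covariance and the Mahalanobis matrix in the
fixed global GPA + PCA space before rebuilding the tree; supports are the
percentage of replicates containing each internal bipartition. Resampling
specimens (not landmarks) is the declared choice because the distances being
bootstrapped are group-mean distances whose sampling error comes from
specimens. Holding the superimposition/PC space fixed across replicates
trades a small amount of variance for speed and stability. When an outgroup
taxon is supplied the tree is rooted at the midpoint of its terminal edge;
rooting happens before supports are attached (rerooting re-wires
parent–child relations and would otherwise detach labels from their
bipartitions). The tree depicts segregation of taxa in shape space, not
phylogeny.

## Synthetic data generator

The generator emulates the study design the package is tested against:
12 species — 4 *Aedes* in 2 subgenera, 3 *Anopheles* in 2 subgenera,
5 *Culex* in 1 subgenus — with per-species sample sizes
(28, 23, 30, 23, 22, 30, 28, 28, 29, 14, 29, 28; total 312) and an optional
20-specimen *Wyeomyia* outgroup.

Each specimen's shape is built in the tangent space at a fixed 18-landmark
template wing:

    template + genus offset + subgenus offset + species offset
             + b · (log size − mean log size) + isotropic noise,

rendered at its realized centroid size and rigidly perturbed (rotation
U(−30°, 30°), translation ±10 template units). Offsets are drawn once per
taxon per dataset, projected into the tangent space, with per-coordinate SDs
genus 0.012 ≫ subgenus 0.005 ≫ species 0.003 against within-specimen noise
0.010. These magnitudes were chosen so pairwise species accuracies span
roughly 60–100% — the qualitative range reported for real congeneric
mosquitoes — with genus-level separation essentially perfect; they are not
fitted to any particular empirical table. Log sizes are normal
(SD 0.08 around a mean of log 300 units) multiplied by a uniform
U(0.8, 1.25) nuisance scale.

The allometric direction b is one fixed unit tangent vector per dataset,
scaled analytically so the expected fraction of total shape variance
attributable to size equals `allometry_fraction` (default 0.0591): with
t = 2k − 4 effective tangent dimensions, level weights w and variance
var_z of realized log size (normal variance plus the closed-form variance of
the log-uniform nuisance scale),

    v_rest = t · (σ_w² + Σ_level σ_level² (1 − Σ_groups w²)),
    |b|²   = f/(1 − f) · v_rest / var_z .

The nuisance scale multiplies the realized size *before* the allometric term
is applied, so measured centroid size is exactly the size the shape responds
to; applying an independent scale after the fact would be an
errors-in-variables corruption making the injected fraction unrecoverable by
the very regression the generator exists to test.

What the generator does not emulate: correlated landmark error (digitizing
error is isotropic here), taxon-specific covariance structure, group-specific
allometric slopes, measurement-unit heterogeneity between sites, and any
resemblance of the template to a real wing's landmark map. Passing tests
therefore demonstrate the correctness and calibration of the algorithms
under the model's assumptions, not that any particular accuracy will be
attained on real specimens.

## Problem sizes and determinism

Calibration tests use 50 replicates of the full 312-specimen design for
allometry recovery, 400 reduced replicates (n = 60, 999 permutations) for
type-I error, 20 seeds per point for classification monotonicity, and
10 seeds for genus-clade recovery; these sizes keep Monte-Carlo standard
errors small relative to the tested tolerances. All randomness flows from
explicit seeds (`numpy.random.default_rng`); the pipeline derives per-stage
seeds from one master seed, records it in the manifest, and writes plots
with fixed metadata so a rerun of the same configuration reproduces every
output byte-for-byte.

## Known limitations

- 2-D landmarks only; no semilandmarks, no missing-landmark estimation.
- Linear discriminants only (no quadratic or regularized covariance
  estimators), LOO only (no k-fold).
- The permutation stand-in for the species table's p-value is not the same
  test a parametric MANOVA would give, though it addresses the same null.
- Tangent-space linearization assumes small shape variation; gross shape
  differences (e.g. across families) would need curved-space methods.
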