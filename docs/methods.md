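# Methods

This note documents the models, numerical choices and limitations of
`surfmorph`, in the order the pipeline runs them.

## Geometric chain

**Surface extraction.** Meshes come from marching cubes at the 0.5
iso-level. The half-occupancy isosurface of a raw binary grid carries a
staircase bias (a voxelised sphere meshes ~8% too much area), so the
occupancy is Gaussian pre-smoothed by 0.7 voxels first; with that choice a
radius-10-voxel sphere meshes within ~1% of its analytic area and an
ellipsoid's enclosed volume is within ~2% at ≥32 voxels per axis. If the
smoothed field no longer crosses the iso-level (structures a voxel or two
thick) extraction falls back to the raw binary volume, so minimal masks
still produce closed surfaces. The volume is zero-padded before extraction
(surfaces touching the grid boundary close), and only the largest
edge-connected component is kept, since real segmentations contain speckle.
Coordinates are physical mm: `x = index · spacing + origin`, 0-based.

**Smoothing.** Umbrella-operator Laplacian, default λ = 0.5 and 10
iterations — there is no canonical choice for these, so both are exposed
as parameters; smoothing never changes topology.

**Closest points.** Thickness and template propagation need exact
point-to-surface distances. A nearest-vertex query gives an upper bound;
every triangle whose centroid sphere could beat that bound is then checked
with a vectorised exact point-triangle test (Ericson's region
classification). The result is the exact triangle-soup minimum — no
vertex-only approximation — at roughly 10⁴ queries per second against
10⁴-triangle meshes without any C extension.

## Correspondence

Registration is ICP with SVD-Procrustes steps (rigid) followed by a
12-parameter least-squares affine refinement; both keep the best iterate,
so the affine objective never exceeds its rigid initialisation. ICP is a
local optimiser, so the rigid stage starts from the identity plus the four
proper principal-axes alignments and refines the two most promising starts;
this recovers rotations of tens of degrees on asymmetric shapes while
guaranteeing that identical inputs return the identity.

The template is the reference topology with each vertex moved to the mean
of its exact closest points on every aligned construction subject — one
averaging pass, since the template serves only as a referencing space.
Alignment during template construction is rigid by default: thickness is a
mm-scale phenotype, and removing subject size with an affine step would
collapse the mean shape onto the reference (the two-concentric-spheres
check — template radius 50 from subjects at 40 and 60 — fails under
affine alignment, which is why rigid is the default and affine an option).

Subject correspondence is closest-point projection of the template onto the
affinely aligned subject surface, recorded as (face, barycentric) pairs.
This **replaces free-form non-rigid registration**: for star-shaped
surfaces the projection is a bijection onto the subject surface and
satisfies the fixed-vertex-count contract exactly (projection is idempotent
to machine precision). For strongly non-convex anatomy closest-point
correspondence can fold; that is a known fidelity gap of this package, not
of the analysis design. Because the affine transform does not preserve
distances, thickness is always measured after mapping resampled vertices
back to the subject's native frame.

## Thickness, QC and phenotype rules

Thickness at an outer vertex is the minimum Euclidean distance to the inner
surface. The closest-point definition (rather than tracing the vertex
normal) is robust to noisy normals; a normal-ray variant is provided for
comparison. QC excludes a subject when its per-subject **maximum** vertex
thickness strictly exceeds the threshold — either an explicit ceiling
(default 154 mm, the 99.9th-percentile ceiling used in large adult imaging
cohorts) or a stated percentile of the cohort's per-subject maxima. A
percentile rule needs a per-subject summary statistic; the maximum is the
conservative choice here (it flags any single aberrant vertex) and is
declared in the QC report. The lipodystrophy indicator is FMR > 1.2
(women) / > 1.7 (men), strict inequality at the boundary.

## Statistical parametric maps

All continuous design columns and every response vertex are z-scored
(n−1 denominator) before fitting; binary indicators stay on their category
scale. Coefficients are reported both standardised and back-transformed
(× per-vertex response SD), giving mm per covariate SD or mm per category.
The vertex-wise OLS runs through one shared pseudo-inverse; exact fits are
guarded to large finite t values.

TFCE uses the canonical surface parameters E = 0.5, H = 2 with
dh = h_max/100 per map (observed and each permuted map normalised the same
way — the usual randomise-style choice). The integral is evaluated by an
incremental union-find over vertices sorted by statistic (numba), exact
with respect to the explicit threshold-loop definition (tested to 1e-9
against a brute-force oracle) and ~1 ms per 2,500-vertex map. Extent is
vertex count by default (matching "percentage of vertices" reporting);
area-weighted extent is available.

Inference is Freedman–Lane: residuals of the nuisance-only model are
permuted with a seeded generator, the full model is refit, and both signed
TFCE maps are compared against their permutation distributions,
`p_v = (1 + #{TFCE*_v ≥ TFCE_v}) / (n_perm + 1)`. Per-sign maps reproduce
sign-split significance areas; BH-FDR is applied within each sign map
rather than pooled across covariates — the self-contained choice, so each
covariate's map stands on its own. Inference is per-vertex permutation p
values with FDR, not max-statistic FWE, matching how signed significance
areas are reported.

Under the global null (200 subjects, ~2,500 vertices, 500 permutations,
20 replicates) the vertex-wise false-positive rate at p < 0.05 is
calibrated; note TFCE couples neighbouring vertices and all vertices share
one permutation set, so the sampling error of the mean FPR is assessed with
the empirical replicate SE, not a pooled binomial SD, which would be
invalid under that correlation.

## Longitudinal mixed models

Per vertex: `y_iv = x_ivᵀβ + b_i + ε_iv` with a subject random intercept
only. REML profiles the ratio ρ = σ_b²/σ²: the per-subject marginal
covariance `I + ρ 1 1ᵀ` has a Woodbury inverse, so each profile evaluation
is a cheap GLS solve; a coarse log-spaced grid brackets the optimum and a
bounded scalar minimisation refines it (tested against a dense grid scan
and against an independent general-purpose mixed-model implementation).
Wald p values use the normal reference — at the cohort sizes this targets
(thousands of observations) the difference from a t/Satterthwaite reference
is negligible; at very small n the p values are mildly anticonservative.
On balanced two-visit data the visit effect equals the paired-difference
estimator identically, which is the fit's sharpest internal check.

## Sparse PCA shape analysis

The thickness matrix is median-centred per vertex — robustness enters
through the centring and an optional winsorisation of scores at 4 MADs;
robust-sparse-PCA variants differ across the literature, so the classical
limit below is kept as the verifiable anchor. Each component is a rank-1
alternating regression: scores `u = Xv`, loadings
`v ← soft_threshold(Xᵀu, λ·‖Xᵀu‖_∞)` renormalised, iterated to
convergence, with projection deflation between components. At λ = 0 this
is exact power iteration, so component variances and loadings match
classical PCA/SVD to machine precision — the property the tests pin at
1e-6. Loadings carry a deterministic sign convention (largest-magnitude
entry positive). Explained variance of correlated sparse components uses
the QR-adjusted (regression-projection) definition to avoid double
counting. Strata (e.g. sex × disease cohort) are handled by fitting one
model per stratum.

## Survival comparison

Cox models use Efron tie handling and Wald 95% CIs (the de facto
defaults), with continuous covariates z-scored so HRs read per SD; fitting
is delegated to lifelines, while tests verify coefficients against a
brute-force partial-likelihood grid search. The volume model is
adjustments + total tissue volume; the thickness model replaces volume with
the first 4 (configurable, e.g. 25) standardised PC scores. Total muscle
volume may not enter the thickness model (collinear with the shape scores
by construction) — config validation enforces this. Models are compared by
partial-likelihood AIC and Harrell's c-index; BH-FDR is applied across the
HR p values per model. The generator's planted studies show the intended
discrimination: a hazard acting through a volume-neutral redistribution
mode is invisible to the volume model and recovered by the PC model; a
hazard through uniform inflation is captured by volume with fewer degrees
of freedom, so volume wins on AIC.

## Synthetic cohorts — what they emulate and what they do not

Subjects are nested ellipsoids: the inner (body-cavity) surface has fixed
semi-axes (55, 45, 40 mm) on a 64³ grid of 3 mm voxels; the outer surface
extends it radially by `base (20 mm) + Σ_j β_j z_j bump_j(u) + noise`.
Effect regions are angular caps with raised-cosine falloff (or top-hat
profiles where a constant planted effect is wanted); because the thickness
function is analytic in the direction `u`, every downstream estimate has an
exact oracle. Covariates mimic a late-middle-aged imaging cohort (age
64 ± 7.5 y; prevalences: hypertension 0.37, type-2 diabetes 0.055,
lipodystrophy ≈ 0.11 via the sex-specific FMR rule); effects are declared
in mm per SD using the declared moments.

Two noise models are used deliberately. Voxel-level masks perturb thickness
with a smooth random angular field (48 raised-cosine bumps, amplitude
normalised to the declared marginal SD) — surfaces must stay meshable.
The matrix-level generator (`generate_cohort_thickness`) evaluates the same
planted model directly at template vertex directions with iid per-vertex
noise, emulating post-registration residual variation; this is what makes
population-scale permutation studies (200 subjects × 2,500 vertices × 500
permutations × 20 replicates) tractable on one CPU, and it is the path the
statistical stages are validated on. Default desk scale: 64³ grids,
~2,500-vertex templates (icosphere remeshing budget), n = 200 subjects,
500 permutations.

What passing tests therefore show: the estimators recover planted effects
of realistic size under Gaussian noise on star-shaped geometry, with
calibrated error rates. What they cannot show: behaviour under real
body-shaped anatomy (arms, non-convexity), registration error that
correlates with the phenotype, non-Gaussian segmentation artefacts, or
informative missingness — complete-case analysis is the only missing-data
policy (the I/O layer refuses tables with missing cells rather than
imputing).

## Determinism and numerical details

Every stochastic component takes an explicit seed; seeds for subject-level
streams derive from the spec seed through `SeedSequence` spawn keys, so
per-subject outputs are independent of generation order. Pipeline artifacts
are byte-stable across reruns (gzip written with mtime 0, canonical JSON,
text VTK with fixed formatting), and each stage manifest records the config
hash and seed; changing any analysis parameter changes the hash. Degenerate
inputs are handled explicitly: zero-variance response vertices are left
unscaled rather than erroring (they arise in noiseless planted checks),
zero-variance design columns error naming the column, empty FDR rejection
sets are legal, and t statistics on exact fits are capped at 1e8.
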