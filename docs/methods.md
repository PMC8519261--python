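# Methods

This note documents the statistical model behind `ctxpls`, the choices
made where the design was genuinely open, what the synthetic generator
does and does not emulate, and the numerical conventions.

## Problem setting

The package addresses a standard imaging-transcriptomics question: do
spatial gene expression patterns of the healthy cortex predict where a
patient cohort shows cortical thickness (CT) change? The predictor is a
region × gene matrix built from point expression samples of a few
donors mapped into a cortical parcellation; the responses are regional
statistics from a patient/control MRI cohort. Because the number of
genes (thousands) vastly exceeds the number of regions (34 per
hemisphere in a Desikan–Killiany-style parcellation) and genes are
strongly collinear, the regression is carried by partial least squares
(PLS) latent components rather than per-gene fits.

## Sample mapping and aggregation

A sample whose MNI coordinate falls inside a labeled voxel takes that
voxel's region. Otherwise it takes the region of the nearest labeled
voxel *center* within a tolerance (default 2 mm, Euclidean, in mm), and
is unassigned beyond it. Distance-to-center was chosen over
distance-to-parcel-surface because it is unambiguous and matches common
practice; ties at exactly equal distance go to the lower region id so
results are platform-independent. The tolerance should be at least half
the voxel diagonal (1.73 mm at 2 mm isotropic voxels) for the recorded
distance of contained samples to respect the tolerance bound.

Aggregation is two-level: mean over a donor's samples within a region,
then mean over the donors that contributed at least one sample there.
Empty (donor, region) cells are excluded from the across-donor mean
rather than imputed — zero is not a valid expression value and
imputation would bias region means toward the panel baseline. Regions
with no samples from any donor are dropped and reported. Genes are put
in canonical sorted order so the matrix is invariant to the input panel
ordering.

## Imaging statistics (the PLS responses)

* **Group contrast.** Per region, a two-sided Welch *t*-test (unequal
  variances, Welch–Satterthwaite df), oriented control − patient so a
  positive *t* means thinner cortex in patients (atrophy). BH step-up
  FDR is applied across exactly the supplied region family (68
  bilateral for reporting; the 34 left-hemisphere values feed the PLS,
  matching the left-only expression matrix).
* **Hemispheric contrast.** Right − left per region, paired *t* by
  default since the same subjects contribute both hemispheres; an
  unpaired Welch mode is available and the mode is recorded in the
  output. An identically zero difference vector is reported as t = 0,
  p = 1 with a zero-variance flag.
* **CT–clinical regression.** For each (region, feature) cell a
  separate OLS `CT = α + β₁·score + β₂·age + ε` on complete cases
  (minimum 4; no imputation, matching the varying per-feature
  availability such data have), testing H₀: β₁ = 0 two-sided. BH spans
  all region × feature cells jointly. Singular designs (e.g. a constant
  age column) are flagged and excluded from the BH family. Sex is
  carried in the tables but not modeled; scores enter untransformed.

## NIPALS PLS

Both blocks are column-centered; unit-variance scaling is optional
(off by default, recorded on the fit). Components are extracted by the
classical NIPALS iteration with deflation of both blocks:

    w ∝ X_kᵀu (unit norm),  t = X_k w,  q = Y_kᵀt / tᵀt,  u ∝ Y_k q
    p_k = X_kᵀt / tᵀt,  X_{k+1} = X_k − t p_kᵀ,  Y_{k+1} = Y_k − t qᵀ

The inner loop runs to a 1e-12 tolerance on the weight-vector change
with a 10,000-iteration cap; the cap is generous because power
iteration converges slowly when the leading singular values of X_kᵀY_k
are nearly tied, and a tightly converged weight vector is required for
the exact-oracle agreement the tests assert. With a single response the
loop converges in one pass and w₁ is the normalized cross-covariance
X_cᵀy_c.

Reported per component: X/Y scores and loadings, the rotated weights
R = W(PᵀW)⁻¹ satisfying T = X_c R (these are the "gene weights" passed
to enrichment — unlike W they refer to the original centered
predictors), the explained-variance fractions ‖t p ᵀ‖²_F/‖X_c‖²_F and
‖t q ᵀ‖²_F/‖Y_c‖²_F, and the inner-relation coefficient. For the inner
relation the classical gauge is used — unit-norm Y-weight c = q/‖q‖,
Y-score u = Y_k c, β_k = uᵀt/tᵀt — because with regression-normalized
loadings the coefficient is identically one and carries no information;
deflation and predictions are gauge-invariant. corr(t_k, u_k) ≥ 0 holds
by construction; in the degenerate zero-correlation case the sign is
fixed by making the largest-magnitude weight entry positive.

Zero-variance predictors are kept (with exactly zero weight) rather
than dropped, preserving gene indexing. At K = rank(X_c) the training
predictions coincide with the least-squares fit — used as an exactness
check.

### Component selection

Leave-one-out cross-validation refits inside every fold (re-centering
included, so no information leaks) and accumulates PRESS per component
count; RMSEP = sqrt(PRESS/(n·p)). Two selections are reported: the
plain RMSEP argmin, and the **one-standard-error rule** (smallest k
whose mean squared prediction error is within one SE — over folds — of
the argmin's), which is the default `optimal_components`. The
motivation is empirical and well known: past the true dimensionality
the CV curve is nearly flat, so the argmin flips to larger k on noise
alone (on planted rank-1 data at 34 regions it picks k = 1 in only
~72% of seeds at any signal-to-noise level, a behavior reproduced
fold-for-fold by an independent scikit-learn-based LOO). The one-SE
rule selects k = 1 in ~98% of those runs while still choosing k ≥ 2
whenever a genuine second factor is present. The same conservative rule
is offered by the R `pls` toolchain.

## Preranked enrichment

Genes are ranked by descending signed weight, ties broken by gene id
(recorded convention). A set's enrichment score is the signed maximum
deviation of the weighted Kolmogorov–Smirnov running sum: members
increment by |w|^γ normalized over the set (γ = 1 by default; γ = 0
gives the unweighted KS statistic), non-members decrement by
1/(N − N_hits); hence ES ∈ [−1, 1]. Because the ranking statistic is a
per-gene weight with no subject-level phenotype behind it, the only
coherent null is gene-label permutation: same-size random draws from
the ranked universe (draws shared across equal-size sets,
seed-deterministic). The p-value is the two-sided tail frequency
|ES_null| ≥ |ES| with a +1 pseudo-count; NES divides ES by the mean
|null ES| of matching sign; FDR is BH over all tested sets. Defaults:
min size 10, max size 500, 10,000 permutations — all configurable and
recorded. A set's direction is the sign of the median member weight
("0" when the median is exactly zero, e.g. an even split), which states
whether the pathway's expression rises or falls along the component —
for model-1, toward atrophy or away from it.

One consequence of the deterministic tie-break worth noting: with a
degenerate all-equal weight vector the ES reduces to the unweighted
position statistic of the tie-broken ranking, so same-size sets at
different rank positions still score differently. That is the correct
behavior of the running-sum definition, not an artifact.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes,
with every output a pure function of the scenario (seed included):

* **Parcellation**: cuboid parcels separated by background voxels on a
  2 mm isotropic grid, region ids increasing along the first axis so
  the planted gradient has a spatial direction ("caudal→rostral").
* **Expression**: sample s in region i has expression
  μ_j + a_j·g_i + ε, ε ~ N(0, σ_expr); g is a zero-mean per-region
  gradient (identifiability convention, enforced), a_j per-gene
  loadings. Per (donor, region) the sample count is zero with
  probability 0.1 (exercising the empty-cell averaging path) and
  1 + Poisson(3) otherwise; coordinates are uniform inside the
  region's voxels.
* **CT cohort**: controls N(base_i, σ_CT), patients
  N(base_i − δ_i, σ_CT), with optional extra left-hemisphere thinning
  for patients; draws are truncated from below at 0.5 mm (CT is
  physically positive; the bound is recorded in the scenario). Defaults
  ~2.5 mm baseline, σ_CT = 0.2 mm, δ = 0.08·g — effect sizes giving
  |t| in the single digits at cohort sizes of hundreds, the regime the
  method targets. Ages are uniform in stated ranges; the sex mix is
  imbalanced between groups but, like in the analysis layer, not
  modeled.
* **Clinical scores**: feature j of patient s is
  Σ_i β₁(j,i)·CT_lh(s,i) + γ_j·age + noise, with missing entries
  injected at a configurable rate (default 0.25) and written as empty
  TSV fields, never zero.

What passing tests on this generator do **not** show: the generator has
no realistic cortical geometry, no spatially autocorrelated noise, no
donor effects or batch structure, no probe-level noise model, and
effect sizes are free parameters rather than calibrated to any real
cohort. Results on real data additionally depend on preprocessing
(probe collapsing, normalization) that is upstream of this package.

### Detection-study conditions

The end-to-end verification uses one fixed scenario family
(`detection_study`): 34 regions, 1,000 genes, 6 donors, 60 + 60
subjects; a planted 25-gene set with loading 0.6 on the gradient,
expression noise 0.3, CT noise 0.2 mm, gradient-proportional δ; 20 gene
sets of 25 and 2,000 permutations. These sizes keep a full pipeline run
under a second while leaving the planted set's detection non-trivial
(component-1/response correlation ≈ 0.77–0.85, not 1). The null
variant zeroes the loadings and the CT effect.

## Numerical conventions and edge cases

* Welch test with both variances zero: flagged; ±∞ statistic (p = 0)
  for distinct means, NaN for equal means.
* BH adjustment validates p ∈ [0, 1] and preserves input order.
* Assignment distances are reported even for unassigned samples
  (distance > tolerance holds by construction).
* LOO folds whose reduced predictor block cannot support the requested
  components are skipped and counted.
* Permutation p-values carry the +1 pseudo-count, so the smallest
  attainable p is 1/(n_perm + 1).
* All stochastic stages take explicit integer seeds; independent
  streams are derived per data modality so regenerating one modality
  never perturbs another.

## Known limitations

* No spatial-autocorrelation-preserving null models for the PLS or the
  enrichment stage; the permutation null treats genes as exchangeable.
* No sparse or regularized PLS, and no permutation test on component
  significance.
* The hemispheric test's paired/unpaired choice and the untransformed
  clinical scores are conventions, recorded in the outputs, not
  validated choices.
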