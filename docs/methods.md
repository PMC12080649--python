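# Methods

This note documents the models, the synthetic-data generator that stands in
for restricted imaging/PET/microarray data, the numerical choices, and the
limits of what the package's tests demonstrate.

## Synthetic study conditions

The generator emulates a two-group (healthy control vs MDD), five-site
structural-MRI study. Regions are centroids on the unit sphere (a Fibonacci
lattice under a seeded random rotation) with great-circle distances; this
carries exactly the information the downstream statistics need — labels and
inter-region distance — without surface meshes.

**Cohort.** Group counts are exact; ages are uniform on [18, 80] years. Each
group's ages are drawn by jittered equal-probability stratification of the
range, so the marginal distribution is exactly uniform but the two groups are
age-matched by construction, as in a case-control sample screened for group
age differences (a screened sample is the setting in which the retrained
permutation test below is meaningful; see "Permutation nulls"). Sites are
assigned round-robin to a shuffled subject order, so each site receives a
near-equal share of both groups.

**Thickness.** For subject *s*, region *r*:

    x[s,r] = β₀_r + β₁_r·age_s + θ_r·1[MDD] + β₁_r·Δ·1[MDD] + γ[site,r] + δ[site,r]·ε[s,r]

with baselines β₀_r ~ N(2.5, 0.25²) mm; age slopes β₁_r = −0.01·U(0.5, 1.5)
mm/yr on a random subset of `n_age_regions` regions (default 200, mirroring
informative features among 372) and 0 elsewhere; a thinning effect
θ_r = −0.2 mm on a spatially contiguous cluster of `n_affected` regions
(default 30) grown by nearest-neighbour selection around a random seed
region; an optional "acceleration" Δ (years) that ages patients along each
region's own slope; additive site shifts γ ~ N(0, 0.1²); multiplicative site
scalings δ = exp(N(0, 0.05²)) applied to the measurement noise
ε ~ N(0, 0.05²). The jittered slopes keep informative features from being
exact copies of one another. Defaults were chosen once as plausible
magnitudes for cortical thickness (≈2.5 mm baseline, ≈1% thinning per
decade, site offsets comparable to twice the measurement noise).

**Receptor maps.** Each map is ρ·z(θ) + √(1−ρ²)·η, where z(θ) is the
standardized true effect map and η is standardized kernel-smoothed white
noise (kernel exp(−d/ℓ), ℓ = 0.5 rad) orthogonalized against z(θ), so the
empirical Pearson correlation with the truth equals the target ρ exactly.
The default nine-map battery assigns nonzero targets (−0.50 … +0.32) to the
five systems the analysis is meant to detect and 0 to the rest.

**Expression.** Signal genes are λ·z(θ) + N(0, σ²) per region (λ = 1,
σ = 0.5 by default); the remaining genes are independent smooth spatial
noise. Default dimensions (10 027 genes × 176 regions) match an AHBA-style
regional matrix. The risk list holds the signal genes plus an equal number
of decoys (60 genes at the default `n_signal = 30`); the annotation
collection plants one term whose membership is 80% signal genes.

What the generator does **not** emulate: hemispheric asymmetry, non-linear
age trajectories, region-wise covariance beyond the planted factor,
probe-level microarray noise, and donor-level expression variability.
Passing tests therefore demonstrate correctness and calibration of the
statistical machinery under the stated model, not performance on real data —
on this clean generator the brain-age model is far more accurate (held-out
r ≈ 0.999, MAE ≈ 1–2.5 yr) than any real-data model.

## ComBat harmonization

Parametric empirical-Bayes location/scale adjustment. Each region is
standardized by an OLS fit with site indicators and covariates (age, sex by
default; the diagnosis indicator is deliberately *excluded* so the group
effect is not partially absorbed — a flag allows including it, at the cost of
shrinking the effect the difference map is meant to measure). Per-site
locations get a normal prior and per-site variances an inverse-gamma prior,
both moment-matched across regions; the coupled posterior updates iterate to
a 1e-6 max-change tolerance (cap 100 iterations). Degenerate priors
(no between-region spread) fall back to the unshrunken estimates, which makes
the two-batch constant-offset case exact to machine precision. Zero-variance
regions pass through unharmonized with a warning.

Two conventions are worth noting. The within-site variance of the
standardized data uses the population (ddof = 0) convention so that fitting
a single site is an identity map to 1e-6; `scale_ddof=1` reproduces the R
reference implementation (`sva::ComBat`), against which the test suite
verifies agreement to 1e-5. Empirical-Bayes shrinkage pulls each location
estimate toward the site's prior mean (a convex combination), which is the
shrinkage property the tests assert.

## Brain-age model and brain-PAD inference

Linear ε-insensitive SVR (C = 1.0, ε = 0.1 yr, tol 1e-4 — the solver's
standard defaults, exposed as parameters since no principled values exist
for this problem), on features z-scored with training statistics only.
Zero-variance training features are dropped and recorded. Training uses
healthy controls only (half of them by default); everyone else is test.
No post-hoc age-bias correction of brain-PAD is applied by default.

**Permutation nulls.** Two modes are provided because the procedure
"shuffle the labels of the training samples and retrain" admits two readings
and they behave very differently:

* `train_ages` (default): shuffle training-set ages, retrain, record the
  test-set brain-PAD group difference. This null is centred near *minus the
  test-set group age difference* (an age-uninformative model predicts a
  near-constant, so its PAD difference is the negated age imbalance), not at
  zero. In an age-matched sample the centre is near zero and the test has
  good power against multi-year effects, but under H0 it is conservative
  (measured rejection ≈ 0 at α = 0.05), and its power degrades when test
  groups are imbalanced in age. This is an inherent property of the design,
  not of the implementation.
* `test_groups`: keep the fitted model, permute test-set diagnosis labels.
  This is the classical exactly-calibrated label permutation (measured
  type-I error ≈ 0.045 over 200 null datasets) and is the mode used for
  calibration tests. One caveat: with a *poorly fitting* model, brain-PAD
  retains a regression-to-mean age trend, and permuting labels in an
  age-matched sample then over-disperses the null (conservative). With an
  adequately fitting model the trend, and the effect, are negligible.

Both report p = (1 + #{|null| ≥ |observed|}) / (n_perm + 1).

## Difference maps

Pooled-variance Student t by default (Welch by flag), sign convention
patients minus controls. Regions whose values are constant within both
groups are excluded from FDR and flagged, never silently dropped. The
regression route fits per-region OLS on [intercept, group, age, sex, site
dummies] with rank checking (collinear columns are named via pivoted QR).
The two routes agree nearly perfectly when age-driven variance is absent;
with strong age slopes the t-test route is attenuated in age-dependent
regions relative to the covariate-adjusted route, so their correlation
settles around 0.85–0.90 under the default conditions — the same order as
cross-method agreement reported for real multi-site data.

BH-FDR is the standard step-up adjustment (via statsmodels), rejection at
adjusted p < q.

## Spatial surrogate null

Parcellated brain maps are spatially autocorrelated, so naive permutation
p-values for map-map correlations are strongly anti-conservative (measured:
> 50% rejection at α = 0.05 for independent smooth map pairs). The null
model here permutes the map, smooths the permutation with kernels
exp(−d/ℓ) over a grid of nine length scales (0 plus a geometric grid up to
the map diameter), selects the scale whose smoothed-and-rank-remapped
candidate minimizes the squared distance to the original's binned variogram
(15 equal-width distance bins), and rank-remaps the candidate onto the
original values. Every surrogate therefore has exactly the original value
multiset and approximately its autocorrelation (median Moran's I within 25%
of the original). Measured calibration on independent autocorrelated pairs:
2.5% rejection at α = 0.05 — slightly conservative, which is the safe side
for claiming receptor associations. The null model is swappable
(`null="permutation"` gives the naive test for comparison).

On a strongly clustered t-map this null is wide: moderate receptor
correlations (|rho| ≈ 0.2–0.4) are generally not significant at desk scale,
and the acceptance script's battery typically reports 0–2 significant maps.
Detection of strongly coupled maps (target ρ = 0.9) is essentially certain.

## PLS transcriptomics

PLS1 by NIPALS with deflation of X only; predictor columns and the response
are z-scored across regions. Signs are fixed so each component's scores
correlate non-negatively with the response. "Variance explained" is the
incremental R² of the response on the cumulative component scores (scores
are orthogonal, so increments are non-negative and sum to ≤ 1); this is the
documented convention behind the reported percentage. Component-1 weights
coincide with the dominant eigenvector of Xᵀy yᵀX, which the tests verify by
brute force, and with scikit-learn's PLS implementation as an independent
cross-check.

Component significance: refit on surrogate responses from the spatial null;
p = (1 + #{varexp_surr ≥ varexp_obs}) / (n_perm + 1). Note that with many
more genes than regions, component 1 explains a large response variance for
*any* response (the high-dimensional fit itself), so a large varexp is not
evidence of signal — only the surrogate comparison is. Under the default
sparse planting (30 signal genes among 10 027) the observed varexp is
typically not distinguishable from the surrogate null at study scale; the
permutation test attains small p when the planted signal is dense relative
to the panel (the regime of the test configurations, e.g. 40 signal genes
among 500). Gene ranking:
bootstrap over regions (the observational units), sign-align each
replicate's weights to the original fit, and rank by the corrected weight
w/SE_boot(w) in descending order ("corrected weight" is interpreted as the
weight standardized by its bootstrap error, the convention of the
bootstrap-PLS literature; the source procedure does not define it).
Degenerate resamples (constant response) are redrawn; a minimum of 50
resamples is enforced.

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) per term, exact against
enumeration for small universes; background defaults to all genes in the
expression matrix; BH across all tested terms pooled over categories
(per-category correction by flag). Terms with no background overlap are
skipped and logged.

## Pipeline

Stages run in fixed order with per-stage sub-seeds derived as the first
state word of `SeedSequence(seed, spawn_key=(stage_index,))` (kept < 2³¹),
so any stage is independently reproducible. All tables are TSV with floats
at 10 significant digits; the manifest records SHA-256 hashes of every
output, and identical config + seed yields identical hashes. The `test`
profile caps n_perm and n_surr at 199 and n_boot at 200; the default test
dimensions (300 subjects, 176 regions, 1000 genes) run the whole pipeline in
well under a minute, and the study-scale acceptance script (670 subjects,
372 regions, 10 027 genes, ~1000 resamples per null) in a few minutes on one
CPU.

## Problem sizes used in the test suite

Simulation-based checks use the smallest sizes at which the property under
test is stable: calibration studies use 60–100 regions and ~200 subjects
over 100–200 replicates; recovery studies use the full 372-region,
600-subject configuration over 50 replicates; exactness checks (hypergeometric
enumeration, eigen oracle, two-batch ComBat) use tiny instances where brute
force is feasible.

## Known limitations

* The surrogate null matches the variogram only approximately; its mild
  conservatism is quantified but not corrected.
* The retrained permutation mode's centring problem (above) means its p-value
  is not comparable across samples with different group age imbalances.
* ComBat assumes additive/multiplicative site effects on a linear
  covariate model; no GAM variant, no missing-data handling.
* The cohort generator draws sites balanced by construction; strongly
  unbalanced site×group designs (where harmonization could absorb group
  signal) are expressible only by editing the cohort table directly.
* Gene sets are tested without ontology-graph propagation.
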