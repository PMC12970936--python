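# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical edge cases.

## Data model and containers

A `MediatorMatrix` holds a participants × mediators table of strictly
positive concentrations (assay units) in which `NaN` marks a below-LOD
nondetect, together with a per-mediator LOD. The container enforces the
core contract at construction: any mediator with nondetects must carry an
LOD. Participant metadata (group, study batch, age, sex, race, BMI,
current smoking, cardiovascular condition, pulmonary-vascular condition,
inhaled-steroid use) live in a plain DataFrame keyed by participant id.

## Synthetic cohorts

The generator draws log2 concentrations from a multivariate normal,

y_ij = b_j + δ_gj + γ_bj + m_bj · ε_ij,   ε ~ N(0, R),

then exponentiates (`exp2`), which guarantees positivity and matches the
pipeline's log2 working scale. Here b_j is the per-mediator baseline
(default: spread over 2–10 log2 units, i.e. ~4 pg/mL to ~1 ng/mL), δ_gj the
planted group shift, γ_bj / m_bj the additive and multiplicative batch
effects (the exact location/scale form the batch-adjustment stage assumes),
and R a block correlation matrix (disjoint blocks of functionally related
mediators sharing a common within-block correlation). Left-censoring then
replaces every value strictly below the per-mediator empirical
`lod_quantile` quantile (default 0.1, capped at 0.25) with a nondetect and
records that quantile as the LOD.

The default roster mirrors a two-study respiratory design: four groups of
25–29 in a "COPD study" batch (pooled control, pre-COPD, GOLD 1/2, GOLD 3)
and three groups of 21–27 in an "e-cig study" batch (control, 3rd-gen
users, 4th-gen users). Planted defaults encode the qualitative pattern the
pipeline targets: inflammatory mediators (+1.5 log2) elevated in GOLD 3;
the protease/elastase axis (MMP-9, MPO, NE, TIMP-1, TIMP-2; +1.0) elevated
in pre-COPD and GOLD 3, with weaker elevations (+0.5 / +0.8) in e-cig
users; chemotactic mediators depressed (−1.0) in 4th-gen users. The 27
default panel names comprise the three functional subsets (7 inflammatory,
10 chemotactic, 4 proteases/enzymes) plus TIMP-1/TIMP-2 and four broad
immune cytokines. Covariates are drawn independently of mediator values by
default (ages ~58 ± 9 in the COPD-study groups vs ~27 ± 6 in the e-cig
groups, comorbidity and steroid prevalences rising with disease stage); an
optional common `age_slope` wires age into the mediator means to exercise
covariate adjustment.

What the generator does **not** emulate: within-participant repeated
measures, heavy-tailed or zero-inflated deviations from lognormality,
covariate–mediator confounding beyond the optional age slope, assay plate
layouts, or sputum cell-count joint distributions. Green tests therefore
demonstrate correctness of the estimators under a well-specified lognormal
world, not robustness to those real-data features.

## Preprocessing

*Detection filter.* A mediator is kept iff detected in ≥ 75% of
participants (inclusive threshold). The operation is idempotent.

*Censored imputation.* Iterative sequential scheme on the log2 scale:
censored cells start at LOD/2; for each of `n_iterations` (default 10)
sweeps, each mediator with nondetects is regressed on all other mediators
by ridge-stabilised least squares (ridge 1e-3 on the normal equations, which
keeps the solve well-posed when mediators are nearly collinear), and its
censored cells are redrawn from N(fitted mean, residual variance) truncated
above at log2(LOD). Draws use a seeded generator; observed cells are never
modified, and every imputed value lies in (0, LOD) by construction. This
keeps the essential structure of censoring-aware sequential imputers
(conditional prediction + truncated draw) without a full Gibbs/elastic-net
machinery; on 10%-censored correlated lognormal data its column-mean bias
is about a third of LOD/2 substitution's (measured in the acceptance
script). When no LOD is supplied by the assay, the per-mediator minimum
observed value is used — a conservative stand-in, since real LODs are at or
below the smallest reportable value.

*Normality.* Shapiro–Wilk W and p per mediator on both raw and log2
scales (scipy's implementation of the standard algorithm; valid for
3 ≤ n ≤ 5000, undefined for constant samples), with a flag for the scale
with higher W. In lognormal data this justifies the log2 working scale.

## Group comparisons

Each endpoint is fit by OLS with treatment coding:
`endpoint ~ group + covariates`. The overall group test is the nested-model
F comparison (full vs covariates-only). Estimated marginal means evaluate
the fit at a single reference covariate profile — continuous covariates at
observed means, categorical covariates at observed level proportions
(prediction at the design-matrix column means). Because all EMMs share that
profile, a pairwise contrast reduces to a difference of group coefficients;
its SE comes from the coefficient covariance and its p-value from a t test
on the residual df (homoscedastic OLS; no Satterthwaite correction).
Benjamini–Hochberg runs within each endpoint's family of C(G,2) contrasts;
no adjustment is applied across endpoints (configurable by adjusting the
returned tables). Missing covariates are handled complete-case per
endpoint, with the dropped count logged and reported. Rank-deficient
designs raise an error naming the collinear covariate. The default
covariate set is age, sex, current smoking, BMI, cardiovascular condition,
pulmonary-vascular condition, and inhaled-steroid use; race is available as
an additional covariate by passing it explicitly.

Note that Benjamini–Hochberg is not idempotent (e.g. BH(0.25, 1.0) =
(0.5, 1.0) but BH(0.5, 1.0) = (1.0, 1.0)); the guaranteed properties are
adjusted ≥ raw, capped at 1, and order preservation.

## Correlation networks

Pearson r between raw (untransformed) concentrations within each group —
raw scale because co-detection of secreted proteins is usually reported on
concentration scale and Pearson r is monotone-invariant only under linear
maps. Two-sided p-values use the exact t transform of r on n−2 df. A pair
is significant iff |r| > 0.6 *and* p < 0.01, both strict; no multiplicity
correction (the joint threshold plays that role). Zero-variance mediators
yield undefined correlations, warned and treated as non-significant. If
nondetects remain (imputation normally precedes this stage),
pairwise-complete observations are used with a warning. Overlap across
groups is reported as UpSet-style exclusive intersections: each pair in the
union is assigned to exactly one group combination, so the combination
counts sum to the union size.

## Batch adjustment

The empirical-Bayes location/scale (ComBat) model on log2 data. Steps:
per-mediator OLS with batch indicators plus the protected design (group
dummies and age by default); standardisation by the sample-size-weighted
grand mean and pooled residual variance; per-batch location (γ̂) and scale
(δ̂) estimates on the standardised data; parametric EB shrinkage — normal
prior on γ, inverse-gamma on δ, hyperparameters by moment matching,
posterior modes via the standard coupled iteration (tolerance 1e-6, max 500
iterations, error on non-convergence); finally subtract γ*, divide by
√δ*, and restore the scale and protected effects. Age is included in the
protected design so age-associated biology is preserved while study-wise
age imbalance cannot masquerade as batch signal. A single batch returns
the input unchanged with a warning; batch confounded with the protected
design raises a rank error. The implementation is pinned against
`sva::ComBat` (agreement to 1e-5 in the test suite) and cross-checked
against scanpy's port.

The control groups of the two studies are pooled into one "Control" label
before adjustment, giving the batches a shared biological anchor.

A property worth knowing: EB shrinkage deliberately leaves a fraction
δ*/(n·τ² + δ*) of each per-mediator batch-mean deviation in place. When
true per-mediator batch effects are nearly identical, τ² reduces to the
sampling variance of γ̂ (∝ 1/n), the shrinkage weight stays near 1/2 at
*any* sample size, and realized post-adjustment batch-mean gaps of a few
tenths of a log2 unit remain — in exchange for γ* estimates that are much
more accurate than the raw per-mediator γ̂. With heterogeneous per-analyte
effects (the realistic case) τ² is dominated by true variation and removal
is nearly complete. `sva::ComBat` behaves identically.

## Clustering

Group × mediator mean matrices (log2, batch-adjusted), optionally
restricted to a functional subset, are row-scaled per mediator (mean 0,
sample SD 1 — the convention of heatmap tools) and clustered
agglomeratively on both axes with Euclidean distance and complete linkage
(the common heatmap defaults; both configurable). Ties in merge heights are
broken lowest-index-first, making results deterministic. Dendrograms are
exported as Newick text plus leaf-order CSVs.

## Mahalanobis similarity and the permutation null

Σ is the pooled within-group sample covariance (group-wise centred
residuals, divisor n − G) over *all* groups, not just the pair under
comparison — the convention of multivariate-distance packages for pairwise
group distances, and the only choice that makes all C(G,2) distances share
one metric. If Σ's condition number exceeds 1e8 a ridge of
1e-6 · trace(Σ)/p is added. Distances are computed by Cholesky whitening of
the group means (mathematically identical to the quadratic form; verified
against the explicit inverse to 1e-10).

Similarities s = 1/d are min-max scaled within each subset: distance
magnitudes scale with subset dimension, so raw values are not comparable
across subsets, while the scaled score fixes the most similar pair at 1 and
the least similar at 0. Zero distances (duplicate group means) and
degenerate scaling (all pairs equidistant) raise errors rather than
producing silent placeholder scores.

The permutation null shuffles group labels across all participants (group
sizes preserved) and recomputes *all* pairwise distances, re-pooling the
covariance from the permuted labels (so the null reflects the full
estimation pipeline; a flag freezes nothing — re-estimation is the only
mode the engine needs since it is cheap). Default 10,000 permutations. The
permuted distances of all pairs within a subset form one pooled null
(configurable to per-pair nulls). A pair's percentile is the fraction of
null draws strictly below its observed distance, ties counted half, ×100;
percentile ≥ 95 flags *far*, ≤ 5 flags *close* (mutually exclusive by
construction since 5 < 95). Under exchangeability both flags calibrate to
their nominal 5% rates (verified by Monte-Carlo in the acceptance checks).

## Pipeline

Stage order: simulate/load → detection filter → imputation → normality →
log2 → adjusted group comparisons → per-group correlation networks and
overlap (raw concentrations, original group labels — correlations describe
each cohort before any cross-study manipulation) → control merging → batch
adjustment → subset-wise clustering → similarity + permutation test (on
log2, batch-adjusted data). One global seed expands into per-stage seeds
via `numpy.random.SeedSequence(seed).generate_state(3)` (simulate, impute,
permutation), each taken modulo 2³¹; identical configurations are
byte-identical across runs, and the manifest records SHA-256 hashes of
every artifact. All tables are RFC-4180 CSV with the participant id in the
first column and empty strings for missing cells.

Default problem sizes (182 participants × 27 mediators, 10,000
permutations per subset) complete in seconds; the test-suite and acceptance
fixtures use 6-group/n=25/10-mediator designs with 1,000 permutations and
up to 200 replicates, sizes at which Monte-Carlo error on a 5% rate is
about ±0.5% — comfortably inside the ±2% tolerance asserted.

## Known limitations

- The imputer is a simplified sequential scheme, not a full Gibbs sampler;
  its uncertainty is not propagated downstream (single imputation).
- EMMs use observed-proportion weighting for categorical covariates;
  balanced ("population") weighting would differ in unbalanced designs.
- The permutation engine assumes exchangeability of participants across
  groups under the null; strong covariate imbalance between groups makes
  the null conservative or liberal in the usual ways.
- Pooled-covariance Mahalanobis assumes comparable within-group covariance
  across groups; strongly heteroscedastic groups distort distances.
- With fewer than ~3 participants per mediator dimension the pooled
  covariance is ill-conditioned and the ridge path engages; distances are
  then shrunk toward Euclidean geometry.
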