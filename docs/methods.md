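# Methods

`epivar` implements a Bayesian variance-partitioning and EWAS pipeline for
complex traits measured alongside high-dimensional omics markers (DNA
methylation arrays, genotype dosages), together with the downstream
machinery such an analysis feeds: epigenetic score construction and
evaluation, a REML cross-estimator, and covariate-adjusted association
suites. Everything is exercised on synthetic cohorts whose generative
structure mirrors the assumptions of the model, so every stage is testable
without access to managed cohort data.

## The mixture regression model

The core model is a whole-genome (here, whole-array) regression

    y = X_1 b_1 + X_2 b_2 + e,    e ~ N(0, s2_e I)

with y the standardized, covariate-residualized trait and X_s the
standardized marker matrix of set s (methylation and/or genotype). Each
effect b_sj follows a spike-plus-mixture prior: a point mass at zero and
three Gaussian components N(0, g_sk * s2_G,s) whose variance fractions
g_sk are fixed a priori at

- methylation: 1e-4, 1e-3, 1e-2 ("small / medium / large" effects),
- genotypes:   1e-5, 1e-4, 1e-3,

with per-set mixture proportions pi_s ~ Dirichlet(1, 1, 1, 1) and
scaled-inverse-chi-square hyperpriors on the effect-variance scale s2_G,s
and the residual variance (nu = 4, scale 0.5 * Var(y) for both — weakly
informative on standardized data; the reference implementations of this
model family do not publish their constants, so ours are documented here
rather than asserted as equivalent).

Gibbs sampling visits every marker in a fresh seeded permutation per sweep
(interleaving both sets in the two-set analysis), samples the mixture
indicator from its marginal full conditional with the effect integrated
out, then the effect from its conditional Gaussian; variances and
proportions follow from conjugate updates. Component log-weights are
max-normalized before exponentiation. The residual vector is maintained
incrementally, giving O(n p) per sweep; the sweep kernel is compiled with
numba. Cohort-scale defaults are 10,000 sweeps, 5,000 burn-in, thinning 5,
four chains, last 250 retained draws per chain combined. Initialization:
b = 0, all indicators in the spike, s2_e = Var(y), pi at its prior mean.

Because markers and trait are standardized (population convention —
divide by n — so that sums of squared effects are variance fractions), the
variance explained by set s in draw t is V_s(t) = sum_j b_sj(t)^2; the
partition reports the mean over retained draws with the 2.5/97.5
percentiles as the 95% credible interval, and splits V_s by the mixture
component each marker currently occupies (the split sums to the total
draw by draw). Summing squared effects per draw and then averaging is
deliberate: squaring the posterior-mean effects instead would discard the
posterior spread (a posterior-mean-squared mode is available for
comparison).

### Correctness oracle

For p <= 8 markers with fixed hyperparameters the posterior is computed
exactly by enumerating all (K+1)^p indicator configurations and the
closed-form Gaussian marginal likelihood (effects integrated out, Woodbury
identity). The Gibbs sampler in fixed-hyperparameter mode must reproduce
the enumerated per-marker inclusion probabilities; the acceptance suite
checks agreement to +/-0.02 on p=5, n=200 fixtures.

### EWAS grouping

Per-marker PIPs are inclusion frequencies over retained draws. Because
physically close, correlated probes split inclusion between themselves,
probes are grouped: leads are taken in descending PIP among markers with
PIP > 0.2, and a lead's group collects still-unassigned same-chromosome
markers within 2.5 kb (closed interval, measured lead-to-member, not
chained) with |Pearson r| > 0.5 against the lead on the analyzed
(residualized, standardized) matrix. The group PIP is the fraction of
draws in which at least one member is non-null — by construction at least
the maximum member PIP — and the group variance contribution is the mean
over draws of the members' summed squared effects. Reported leads must
pass lead PIP > 0.80 and group PIP > 0.95 (both configurable; the
stricter joint rule is the default).

## Preprocessing

- Outlier removal: scores more than 3.5 SD from the column mean are set
  missing, single pass (moments from the untrimmed column; iterating
  would make the rule order-dependent).
- General factor g: first unrotated principal component of the
  column-standardized battery, complete rows only, sign oriented so the
  first test loads positively (needed for a reproducible score sign). The
  variance share of the component is returned.
- Residualization: ordinary least squares with intercept, categoricals
  expanded to indicators; rank deficiency is an error naming the
  collinear columns. The trait is pre-corrected for age, sex, BMI and a
  smoking score; marker columns for batch, age, sex and smoking (genetic
  analyses instead use age, sex and genotype principal components, via
  the same configurable covariate list). Markers are residualized after
  QC and before standardization, so the standardized variable is the
  analyzed one. A helper quantifies the effect of adding a quadratic age
  term as the correlation between the two residual vectors.
- QC: markers then samples dropped below a 95% call rate (order
  configurable), non-autosomal markers removed, genotype markers with
  MAF < 1% removed; a per-rule count report is returned.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

- CpG blocks: an exchangeable one-factor construction (sqrt(rho) shared
  factor + sqrt(1-rho) unique noise) gives within-block correlation rho at
  O(n p) cost; block members sit 500 bp apart, blocks 10 kb apart, so the
  2.5 kb grouping rule exercises both inclusion and exclusion. CpG values
  are continuous (M-value-like); the analysis standardizes them anyway.
- SNPs: Hardy-Weinberg dosages at MAF ~ U(0.01, 0.5).
- Architecture: markers are assigned to {null, small, medium, large} by
  the configured occupancy fractions; effects are drawn from the matching
  Gaussians and rescaled so the realized variance of the standardized
  linear predictor equals the target share exactly (defaults 0.416 for
  methylation, 0.379 for genotypes — the regime of the motivating
  analysis). An overlap parameter can make causal CpG values partially
  driven by the SNP genetic value, since the true overlap between the two
  components is not known; the default is independence.
- Phenotype: latent g = genetic values + covariate effects + scaled
  Gaussian noise; four battery tests load on standardized g (defaults
  0.8/0.7/0.7/0.6 with unique SD sqrt(1-l^2)). Age/sex/BMI/smoking have
  configurable effects on the trait; batch shifts and two latent
  cell-composition factors (loading on a random 20% of CpGs) perturb the
  observed markers only, making them pure technical confounders.
- Ground truth (causal ids, effects, realized shares, latent g, per-set
  genetic values) is recorded; identical seeds give bit-identical
  cohorts.

What the generator does not emulate: realistic LD and co-methylation
maps, beta-value distributions, sex chromosomes, imprinting, family
structure. Passing tests therefore demonstrate calibration and recovery
under the model's own assumptions plus the injected technical
confounding — not robustness to everything real cohorts contain.

## EpiScore and prediction theory

Score weights are the posterior-mean effects per marker with zero draws
included, so weights are shrunk by inclusion frequency (a
conditional-on-inclusion mode exists but is not the default). Projection
onto a target cohort scales each available marker within the target,
zero-imputes missing entries after scaling, and sums weight times value;
markers absent from the target are skipped. Incremental R2 of a score
over a covariate baseline is the difference in ordinary (unadjusted) R2
between nested OLS fits, with a partial-F block test.

The expected out-of-sample prediction R2 for a training sample of N, M
trait-affecting markers and marker-captured variance h2 is

    E[R2] = N h2 / (N h2 + M),

the standard prediction-accuracy closed form; it reproduces 4.0% at
N=10,000, 7.7% at N=20,000 and 29.4% at N=100,000 for M=100,000 and
h2=0.416. The form predicts the squared correlation between the score
and the marker-attributable genetic value, which synthetic truth makes
directly observable; the validation study therefore measures incremental
R2 against that component (and reports the phenotype-level R2, whose
expectation is h2 times smaller, alongside). In the study design
(independent markers, every marker carrying a small effect, so M = p)
the spike-mixture score tracks the curve across N in {500, 1000, 2000}
but is not identical to it: at N h2 / M around 0.1 per-marker
information the spike prior under-uses diffuse signal relative to the
ridge-like estimator the formula assumes (a ridge fit on the same data
matches the curve), and at high information adaptive shrinkage slightly
beats it. Both deviations are about +/-0.05 absolute here, hence the
+/-0.10 acceptance band plus monotonicity.

## REML cross-estimator

The omics relationship matrix A = Z Z^T / p over standardized markers
feeds a one-component linear mixed model y ~ N(mu, s2_A A + s2_e I),
fitted by average-information REML working in the eigenbasis of A (one
symmetric eigendecomposition, O(n) per iteration). Initialization is the
Haseman-Elston regression of phenotype cross-products on off-diagonal
A_ij. AI steps are backtracked if they lower the restricted likelihood; a
damped gradient step with halving is the fallback; parameters pinned at
the positive floor with downhill gradients are frozen (active-set
boundary handling). Convergence: log-likelihood change < 1e-6, max 100
iterations; the accepted-step likelihood sequence is non-decreasing by
construction. The variance share m2 = s2_A / (s2_A + s2_e) is clamped to
[0, 1] and flagged when on the boundary; its SE comes from the inverse AI
matrix by the delta method.

## Association suites

Risk-factor and protein-panel associations are per-outcome OLS fits with
age and sex (plus any further covariates) adjusted, predictor and outcome
standardized by default so estimates are per-SD and comparable across
panels. Skewed outcomes are log-transformed (log(x+1) where zeros occur,
e.g. alcohol units); reverse-coded outcomes flip sign. Protein levels are
rank-based inverse-normal transformed with Blom offsets
((rank - 3/8)/(n + 1/4), ties to average ranks) and residualized on the
covariates before modelling. Panel-wide significance uses Bonferroni
0.05/m with m the panel size; concordance between two predictors is the
Pearson correlation of their per-outcome estimates plus the OLS slope
with 95% CI (a noisier proxy shows slope < 1).

Calibration note: at m = 70 independent null outcomes Bonferroni's
familywise error is 1 - (1 - 0.05/70)^70 ~ 0.0488, so the empirical check
over R replicates allows the binomial sampling band
0.05 + 2 sqrt(0.05 * 0.95 / R).

## Validation study sizes and numerical choices

The replicate studies (in `epivar.experiments`, shared by the test suite
and `scripts/acceptance.py`) use desk-scale designs chosen once:

- Sampler-vs-oracle: p=5, n=200, 50,000 sweeps, fixed hyperparameters.
- Variance-share recovery: 20 replicates at n=2000, p=4000 CpGs,
  target share 0.416; 1100 sweeps / 500 burn-in / 2 chains per replicate
  (coverage of the realized truth by the 95% credible interval, and
  agreement with REML within twice the larger uncertainty). Covariate
  effects on the trait are zeroed in this design so the target share
  refers to the analyzed, pre-corrected phenotype; batch effects still
  perturb the markers and are regressed out. Cell-composition robustness
  is a separate property test.
- Group-PIP EWAS: n=800, p=1000 CpGs in correlated pairs (r=0.9, 500 bp),
  three planted loci of ~6% variance each; 4000 sweeps with 3000 burn-in
  (the mixture proportions need ~2000 sweeps to relax from the
  prior-mean start to the sparse state on null data). Small panels
  (p ~ 200) are avoided deliberately: with few markers the
  spike-vs-smallest-slab split is weakly identified and null inclusion
  inflates — an artefact of tiny panels, not of the method.
- Prediction consistency: N in {500, 1000, 2000} training samples,
  p = M = 2000, n_test = 1000, three seeds per N.
- Association calibration: 500 null panels of 70 proteins (familywise
  error), 20 seeds of a 90-protein panel with 10 planted shared-latent
  associations (overlap recovery).

Degenerate inputs are errors, not silences: constant columns cannot be
standardized or inverse-normal transformed, rank-deficient designs name
their collinear columns, an identity ORM has no off-diagonal information,
and a residual-variance underflow aborts the sampler with its chain and
sweep. Seeds propagate from a single integer through named
SeedSequence-derived streams, so every study is reproducible end to end.

## Known limitations

- Relatedness is not explicitly modelled (no family random effect); the
  mixture prior's implicit control is exercised only against the
  cell-composition and batch confounders the generator injects.
- The two-set analysis shares one residual vector but keeps per-set
  hyperparameters; no cross-set covariance of effects is modelled.
- The sampler requires complete marker data; imputation is upstream.
- Variance partitions ignore cross-marker covariance terms (sums of
  squared effects), matching the reporting convention of the model
  family; under strong within-block correlation the partition and the
  variance of the realized linear predictor can differ slightly.
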