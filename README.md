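# epivar

Bayesian mixture variance partitioning and epigenome-wide association of
complex traits, with epigenetic-score prediction.

## The problem

How much of the person-to-person variation in a complex trait — the
motivating case is general cognitive ability, *g*, derived as the first
principal component of a cognitive test battery — is captured by blood
DNA methylation, over and above common genetic variation? And can a
single blood-based predictor (an "EpiScore") built from those methylation
effects explain trait variance in an independent cohort?

`epivar` is a reusable pipeline for that analysis, aimed at statistical
geneticists and epigenetics researchers. It implements:

- a **spike-plus-Gaussian-mixture penalised regression** (BayesR-style
  Gibbs sampler) over one or two standardized marker sets (methylation
  and/or genotype dosages), with prior per-marker variance fractions
  {1e-4, 1e-3, 1e-2} for CpGs and {1e-5, 1e-4, 1e-3} for SNPs:

      y = X1 b1 + X2 b2 + e,   b_sj ~ pi_s0 d0 + sum_k pi_sk N(0, g_sk s2_Gs)

- **variance partitions** with 95% credible intervals (per draw,
  V_s = sum_j b_sj^2 on standardized data) and marginal-vs-conditional
  attenuation summaries;
- the **group-PIP EWAS** procedure: probes within 2.5 kb and |r| > 0.5 of
  a lead probe (PIP > 0.2) are grouped; the group PIP is the probability
  that at least one member is in the model; leads are reported at lead
  PIP > 0.80 and group PIP > 0.95;
- **EpiScore / polygenic-score projection** (weighted sums over
  within-cohort standardized markers, missing values zero-imputed) with
  incremental-R2 evaluation against covariate and polygenic-score
  baselines, and the closed-form expected prediction R2,
  N h2 / (N h2 + M);
- an **AI-REML estimator** on omics relationship matrices
  (A = Z Z^T / p) as an independent cross-check of the Bayesian
  partition, initialized from Haseman-Elston regression;
- **association suites**: covariate-adjusted regressions against risk
  factors and protein panels, rank-based inverse-normal transforms,
  Bonferroni control, and effect-concordance summaries;
- a **synthetic cohort generator** (correlated CpG blocks with genomic
  positions, Hardy-Weinberg SNPs, sparse mixture architectures with exact
  realized variance shares, covariate/batch/cell-composition
  confounding, a multi-test battery loading on a latent factor) with full
  ground-truth records, so every stage above is testable end to end.

See `docs/methods.md` for the model, priors, numerical choices and the
validation study designs.

## Worked example

```python
from epivar import (
    ConfounderSpec, SimulationConfig, simulate_cohort,
    GibbsConfig, run_gibbs, variance_partition, MarkerMatrix,
)
from epivar import preprocess

# a cohort where methylation explains 41.6% of the analyzed trait
config = SimulationConfig(
    n_samples=1000, n_cpg=1000, n_snp=0,
    target_var_epi=0.416, target_var_gen=0.0,
    confounders=ConfounderSpec(age_pheno=0, sex_pheno=0, bmi_pheno=0,
                               smoking_pheno=0, cell_marker_sd=0),
    seed=7,
)
observed, pheno, truth = simulate_cohort(config)

covs = pheno[["age", "sex", "smoking", "bmi"]].copy()
covs["batch"] = pheno["batch"].astype(str)
markers = preprocess.standardize(
    MarkerMatrix(preprocess.residualize(observed.values, covs),
                 observed.manifest.copy(), standardized=False))
y = preprocess.standardize_vector(
    preprocess.residualize(truth.latent_g, covs)).to_numpy()

draws = run_gibbs(y, markers, config=GibbsConfig(
    n_iter=1500, burn_in=700, thin=2, n_chains=2, retain_last=250, seed=1))
part = variance_partition(draws)["methylation"]
print(f"variance explained: {part.mean:.3f} "
      f"[{part.ci_low:.3f}, {part.ci_high:.3f}]  (truth {truth.realized_var_epi:.3f})")
```

This prints (machine-exact values depend only on the seeds):

```
variance explained: 0.397 [0.330, 0.475]  (truth 0.424)
```

i.e. the posterior mean variance share is 0.397 with a 95% credible
interval [0.330, 0.475] that covers the realized simulated share 0.424.
The closed-form prediction curve is one call:

```python
from epivar import theoretical_r2, PredictionSpec
theoretical_r2(PredictionSpec(10_000, 100_000, 0.416))  # 0.0399 -> "about 4%"
```

A thin CLI mirrors the stages (`epivar simulate / preprocess / fit /
summarise / score / predict-curve / reml`); run `epivar --help`.

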