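"""End-to-end validation studies run on synthetic cohorts.

Each function builds its own data with the generator, runs the relevant
pipeline stages and returns measured quantities.  They are used both by
the test suite and by the reproduction script, so the study designs —
sample sizes, marker counts, sweep counts — live here in one place.
Sweep counts are desk-scale: enough for the Monte-Carlo error of the
summaries being checked, chosen once per study.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import episcore, preprocess, reml, sim, summaries
from .containers import MarkerMatrix
from .gibbs import GibbsConfig, MixtureSpec, enumerate_posterior_oracle, run_gibbs


def _child_seed(seed: int, *tags) -> int:
    import zlib

    parts = [seed] + [
        zlib.crc32(t.encode()) if isinstance(t, str) else int(t) for t in tags
    ]
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31 - 1))


def _standardized_marker_matrix(x: np.ndarray, prefix: str = "m", spacing: int = 10_000):
    """Wrap a raw array as a standardized single-chromosome methylation matrix."""
    n, p = x.shape
    man = pd.DataFrame(
        {
            "id": [f"{prefix}{j:05d}" for j in range(p)],
            "chr": "1",
            "pos": [1_000_000 + j * spacing for j in range(p)],
            "set": "methylation",
        }
    )
    vals = pd.DataFrame(x, index=[f"S{i:05d}" for i in range(n)], columns=man["id"])
    mm = MarkerMatrix(vals, man, standardized=False)
    return preprocess.standardize(mm)


def _standardize_y(y: np.ndarray) -> np.ndarray:
    return (y - y.mean()) / y.std()


# ---------------------------------------------------------------------------
# sampler vs enumeration oracle


def oracle_equivalence(seed: int, n: int = 200, p: int = 5, sweeps: int = 50_000) -> dict:
    """Gibbs PIPs vs exact enumeration on a small fixed-hyperparameter fixture.

    Mixed signal: two strong markers, one weak, two null.  Hyperparameter
    updates are disabled so both routes target the same posterior.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    markers = _standardized_marker_matrix(x)
    z = markers.values.to_numpy(float)
    beta_true = np.array([0.35, 0.25, 0.1, 0.0, 0.0])[:p]
    y = _standardize_y(z @ beta_true + rng.standard_normal(n))

    gamma = (0.001, 0.01, 0.1)
    sigma2_g, sigma2_e = 1.0, 0.8
    pi = np.array([0.7, 0.1, 0.1, 0.1])

    exact_pips, _ = enumerate_posterior_oracle(y, z, gamma, sigma2_g, sigma2_e, pi)

    burn = sweeps // 5
    thin = 4
    config = GibbsConfig(
        n_iter=sweeps,
        burn_in=burn,
        thin=thin,
        n_chains=1,
        retain_last=(sweeps - burn) // thin,
        seed=seed,
    )
    spec = MixtureSpec(gamma={"methylation": gamma})
    draws = run_gibbs(
        y,
        markers,
        spec=spec,
        config=config,
        fix_hyperparameters={"sigma2_g": [sigma2_g], "sigma2_e": sigma2_e, "pi": pi},
    )
    gibbs_pips = summaries.marker_pips(draws).to_numpy()
    return {
        "gibbs_pips": gibbs_pips,
        "exact_pips": exact_pips,
        "max_abs_dev": float(np.abs(gibbs_pips - exact_pips).max()),
    }


# ---------------------------------------------------------------------------
# variance-share recovery (Bayesian + REML)

RECOVERY_GIBBS = GibbsConfig(n_iter=1100, burn_in=500, thin=2, n_chains=2, retain_last=250)


def recovery_config(seed: int, n: int = 2000, p_cpg: int = 4000) -> sim.SimulationConfig:
    """Methylation-only cohort with a 0.416 variance share.

    Covariate effects on the trait are zeroed so the target share refers
    to the analyzed (pre-corrected) phenotype; batch still perturbs the
    observed markers and is regressed out, which is the correction the
    pipeline is meant to absorb.
    """
    return sim.SimulationConfig(
        n_samples=n,
        n_cpg=p_cpg,
        n_snp=0,
        target_var_epi=0.416,
        target_var_gen=0.0,
        confounders=sim.ConfounderSpec(
            age_pheno=0.0,
            sex_pheno=0.0,
            bmi_pheno=0.0,
            smoking_pheno=0.0,
            batch_marker_sd=0.2,
            cell_marker_sd=0.0,
        ),
        seed=seed,
    )


def prepare_recovery_inputs(config: sim.SimulationConfig):
    """Simulate, pre-correct and standardize one recovery cohort."""
    observed, pheno, truth = sim.simulate_cohort(config)
    covs = pheno[["age", "sex", "smoking", "bmi"]].copy()
    covs["batch"] = pheno["batch"].astype(str)
    marker_resid = preprocess.residualize(observed.values, covs)
    markers = preprocess.standardize(
        MarkerMatrix(marker_resid, observed.manifest.copy(), standardized=False)
    )
    y_resid = preprocess.residualize(truth.latent_g, covs)
    y = preprocess.standardize_vector(y_resid).to_numpy()
    return markers, y, truth


def recovery_replicate(seed: int, n: int = 2000, p_cpg: int = 4000, run_reml: bool = True) -> dict:
    """One seeded replicate of the variance-share recovery study."""
    config = recovery_config(seed, n=n, p_cpg=p_cpg)
    markers, y, truth = prepare_recovery_inputs(config)
    gibbs_config = GibbsConfig(**{**RECOVERY_GIBBS.__dict__, "seed": seed})
    draws = run_gibbs(y, markers, config=gibbs_config)
    part = summaries.variance_partition(draws)["methylation"]
    out = {
        "truth": truth.realized_var_epi,
        "mean": part.mean,
        "ci_low": part.ci_low,
        "ci_high": part.ci_high,
        "covered": bool(part.ci_low <= truth.realized_var_epi <= part.ci_high),
        "mixture_means": part.mixture_means,
    }
    if run_reml:
        orm = reml.compute_orm(markers)
        fit = reml.reml_fit(y, orm)
        out["reml_m2"] = fit.m2
        out["reml_se"] = fit.se
    return out


def recovery_study(seed: int, n_replicates: int = 20, n: int = 2000, p_cpg: int = 4000) -> dict:
    """Coverage of the 95% credible interval and REML concordance."""
    reps = [
        recovery_replicate(_child_seed(seed, "recovery", r), n=n, p_cpg=p_cpg)
        for r in range(n_replicates)
    ]
    means = np.array([r["mean"] for r in reps])
    remls = np.array([r["reml_m2"] for r in reps])
    ci_half = np.array([(r["ci_high"] - r["ci_low"]) / 2 for r in reps])
    reml_se = np.array([r["reml_se"] for r in reps])
    combined = np.sqrt(ci_half**2 + (1.96 * reml_se) ** 2)
    return {
        "replicates": reps,
        "n_covered": int(sum(r["covered"] for r in reps)),
        "n_replicates": n_replicates,
        "mean_bayes": float(means.mean()),
        "mean_reml": float(remls.mean()),
        "mean_truth": float(np.mean([r["truth"] for r in reps])),
        "reml_agree": int(np.sum(np.abs(means - remls) <= 2 * np.maximum(ci_half, 1.96 * reml_se))),
        "combined_uncertainty": float(combined.mean()),
    }


# ---------------------------------------------------------------------------
# group-PIP EWAS recovery

# the long burn-in lets the mixture proportions relax from the prior-mean
# start (spike weight 0.25) to the sparse state before draws are retained
GROUP_GIBBS = GibbsConfig(n_iter=4000, burn_in=3000, thin=2, n_chains=2, retain_last=250)


def _planted_cohort(seed: int, n: int = 800, n_cpg: int = 1000):
    """Three causal loci, each a pair of near-duplicate probes 500 bp apart.

    The marker count is kept large enough (1000) that the spike proportion
    of the mixture is well identified; with very few markers the posterior
    on the spike-vs-smallest-slab split wanders and null inclusion rates
    inflate, which is an artefact of tiny panels rather than of the method.
    """
    config = sim.SimulationConfig(
        n_samples=n,
        n_cpg=n_cpg,
        n_snp=0,
        block_size=2,
        block_rho=0.9,
        target_var_epi=0.0,
        target_var_gen=0.0,
        confounders=sim.ConfounderSpec(batch_marker_sd=0.0, cell_marker_sd=0.0),
        seed=seed,
    )
    markers = preprocess.standardize(sim.simulate_markers(config))
    z = markers.values.to_numpy(float)
    # lead probes of three well-separated blocks
    causal_cols = [0, (n_cpg // 3) // 2 * 2, (2 * n_cpg // 3) // 2 * 2]
    rng = np.random.default_rng(_child_seed(seed, "planted-pheno"))
    beta = 0.25  # each locus explains ~6% of the trait variance
    signal = z[:, causal_cols].sum(axis=1) * beta
    noise = rng.standard_normal(n) * np.sqrt(max(1 - 3 * beta**2, 0.1))
    y = _standardize_y(signal + noise)
    blocks = [{causal_cols[i], causal_cols[i] + 1} for i in range(3)]
    return markers, y, blocks


def group_recovery_replicate(seed: int, null: bool = False, n: int = 800, n_cpg: int = 1000) -> dict:
    """EWAS grouping on a planted (or null) cohort.

    Success on planted data: the groups with group PIP > 0.95 are exactly
    one per planted locus, each led by a probe of that locus.  On null
    data the default lead report must be empty.
    """
    markers, y, blocks = _planted_cohort(seed, n=n, n_cpg=n_cpg)
    if null:
        rng = np.random.default_rng(_child_seed(seed, "null-pheno"))
        y = _standardize_y(rng.standard_normal(n))
    gibbs_config = GibbsConfig(**{**GROUP_GIBBS.__dict__, "seed": seed})
    draws = run_gibbs(y, markers, config=gibbs_config)
    groups = summaries.group_probes(draws, markers)
    leads = summaries.report_leads(groups)
    strong = [g for g in groups if g.group_pip > 0.95]
    col_of = {mid: j for j, mid in enumerate(markers.values.columns)}
    hit_blocks = set()
    clean = True
    for g in strong:
        lead_col = col_of[g.lead]
        which = [i for i, b in enumerate(blocks) if lead_col in b]
        if which:
            hit_blocks.add(which[0])
        else:
            clean = False
    return {
        "n_strong_groups": len(strong),
        "planted_recovered": bool(clean and hit_blocks == {0, 1, 2} and len(strong) == 3),
        "n_reported_leads": len(leads),
        "groups": groups,
    }


def group_recovery_study(seed: int, n_seeds: int = 20) -> dict:
    planted = [
        group_recovery_replicate(_child_seed(seed, "grp", r)) for r in range(n_seeds)
    ]
    nulls = [
        group_recovery_replicate(_child_seed(seed, "grpnull", r), null=True)
        for r in range(n_seeds)
    ]
    return {
        "planted_success": int(sum(r["planted_recovered"] for r in planted)),
        "null_zero_leads": int(sum(r["n_reported_leads"] == 0 for r in nulls)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# out-of-sample prediction vs the closed-form expectation

PREDICTION_GIBBS = GibbsConfig(n_iter=900, burn_in=400, thin=2, n_chains=2, retain_last=250)


def prediction_replicate(seed: int, n_train: int, n_test: int = 1000, p_cpg: int = 2000) -> dict:
    """Train an EpiScore at one sample size and measure test-set R2 gain.

    Uses a dense architecture (every CpG carries a small effect, so
    M = p) on independent markers — the regime in which the expected
    prediction R2 of N h2 / (N h2 + M) is derived.  The closed form
    predicts the score's squared correlation with the marker-attributable
    genetic value, so ``delta_r2`` is the incremental R2 for that
    component; ``delta_r2_phenotype`` (incremental R2 for the full trait,
    whose expectation is h2 times smaller) is reported alongside.
    """
    config = sim.SimulationConfig(
        n_samples=n_train + n_test,
        n_cpg=p_cpg,
        n_snp=0,
        block_size=1,
        block_rho=0.0,
        mixture_fractions_epi=(0.0, 1.0, 0.0, 0.0),
        target_var_epi=0.416,
        target_var_gen=0.0,
        confounders=sim.ConfounderSpec(
            age_pheno=0.0,
            sex_pheno=0.0,
            bmi_pheno=0.0,
            smoking_pheno=0.0,
            batch_marker_sd=0.0,
            cell_marker_sd=0.0,
        ),
        seed=seed,
    )
    observed, pheno, truth = sim.simulate_cohort(config)
    ids = list(observed.values.index)
    train_ids, test_ids = ids[:n_train], ids[n_train:]

    train = preprocess.standardize(
        MarkerMatrix(
            observed.values.loc[train_ids], observed.manifest.copy(), standardized=False
        )
    )
    y_train = _standardize_y(truth.latent_g.loc[train_ids].to_numpy())
    gibbs_config = GibbsConfig(**{**PREDICTION_GIBBS.__dict__, "seed": seed})
    draws = run_gibbs(y_train, train, config=gibbs_config)
    weights = episcore.extract_weights(draws)

    test = MarkerMatrix(
        observed.values.loc[test_ids], observed.manifest.copy(), standardized=False
    )
    score, n_overlap = episcore.project_score(weights, test)
    baseline = pheno.loc[test_ids, ["age", "sex"]]
    g_epi = truth.genetic_values["methylation"].loc[test_ids]
    res_component = episcore.incremental_r2(g_epi, baseline, score)
    res_pheno = episcore.incremental_r2(truth.latent_g.loc[test_ids], baseline, score)

    m_true = len(truth.causal_ids["methylation"])
    theory = episcore.theoretical_r2(
        episcore.PredictionSpec(n_train, m_true, truth.realized_var_epi)
    )
    return {
        "n_train": n_train,
        "delta_r2": res_component["delta_r2"],
        "delta_r2_phenotype": res_pheno["delta_r2"],
        "theory": theory,
        "m_true": m_true,
        "h2_true": truth.realized_var_epi,
        "n_overlap": n_overlap,
    }


def prediction_study(seed: int, n_values=(500, 1000, 2000), n_seeds: int = 3) -> dict:
    """Mean test-set R2 gain against the closed form across sample sizes."""
    rows = []
    for n_train in n_values:
        reps = [
            prediction_replicate(_child_seed(seed, "pred", n_train, r), n_train)
            for r in range(n_seeds)
        ]
        rows.append(
            {
                "n_train": n_train,
                "delta_r2": float(np.mean([r["delta_r2"] for r in reps])),
                "delta_r2_sd": float(np.std([r["delta_r2"] for r in reps])),
                "delta_r2_phenotype": float(np.mean([r["delta_r2_phenotype"] for r in reps])),
                "theory": float(np.mean([r["theory"] for r in reps])),
            }
        )
    return {"curve": rows}


# ---------------------------------------------------------------------------
# association-suite calibration

def association_null_fwer(seed: int, n_replicates: int = 500, n: int = 500, panel: int = 70) -> dict:
    """Familywise error of the Bonferroni-corrected panel under the null."""
    from .assoc import protein_assoc

    hits = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(_child_seed(seed, "fwer", r))
        idx = pd.RangeIndex(n)
        scores = pd.DataFrame({"score": rng.standard_normal(n)}, index=idx)
        proteins = pd.DataFrame(
            rng.standard_normal((n, panel)),
            index=idx,
            columns=[f"prot_{j}" for j in range(panel)],
        )
        covs = pd.DataFrame(
            {"age": rng.normal(70, 5, n), "sex": rng.integers(0, 2, n).astype(float)},
            index=idx,
        )
        res = protein_assoc(scores, proteins, covs)
        hits += int(res["significant_counts"]["score"] > 0)
    return {"fwer": hits / n_replicates, "n_replicates": n_replicates}


def association_planted_recovery(
    seed: int, n_seeds: int = 20, n: int = 500, panel: int = 90, n_planted: int = 10
) -> dict:
    """Overlap recovery of proteins driven by a latent shared with both predictors."""
    from .assoc import protein_assoc

    successes = 0
    for r in range(n_seeds):
        rng = np.random.default_rng(_child_seed(seed, "planted", r))
        idx = pd.RangeIndex(n)
        latent = rng.standard_normal(n)
        scores = pd.DataFrame(
            {
                "episcore": 0.8 * latent + 0.6 * rng.standard_normal(n),
                "measured_g": 0.9 * latent + np.sqrt(1 - 0.81) * rng.standard_normal(n),
            },
            index=idx,
        )
        prot = rng.standard_normal((n, panel))
        planted_cols = list(range(n_planted))
        for j in planted_cols:
            prot[:, j] = 0.35 * latent + np.sqrt(1 - 0.35**2) * rng.standard_normal(n)
        proteins = pd.DataFrame(prot, index=idx, columns=[f"prot_{j}" for j in range(panel)])
        covs = pd.DataFrame(
            {"age": rng.normal(70, 5, n), "sex": rng.integers(0, 2, n).astype(float)},
            index=idx,
        )
        res = protein_assoc(scores, proteins, covs)
        planted_names = {f"prot_{j}" for j in planted_cols}
        successes += int(set(res["overlap"]) == planted_names)
    return {"recovery_rate": successes / n_seeds, "n_seeds": n_seeds}
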