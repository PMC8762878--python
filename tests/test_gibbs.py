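import numpy as np
import pandas as pd
import pytest

from epivar import preprocess, summaries
from epivar.containers import MarkerMatrix
from epivar.gibbs import (
    GibbsConfig,
    MixtureSpec,
    convergence_diagnostics,
    enumerate_posterior_oracle,
    run_gibbs,
)
from tests.conftest import make_draws


def _markers_from_array(x, prefix="m"):
    n, p = x.shape
    man = pd.DataFrame(
        {
            "id": [f"{prefix}{j}" for j in range(p)],
            "chr": "1",
            "pos": np.arange(p) * 10_000 + 1,
            "set": "methylation",
        }
    )
    vals = pd.DataFrame(x, index=[f"S{i}" for i in range(n)], columns=man["id"])
    return preprocess.standardize(MarkerMatrix(vals, man))


def _std(y):
    return (y - y.mean()) / y.std()


class TestSpecValidation:
    def test_gamma_must_increase(self):
        with pytest.raises(ValueError):
            MixtureSpec(gamma={"methylation": (0.01, 0.001, 0.1)})

    def test_retention_budget(self):
        with pytest.raises(ValueError):
            GibbsConfig(n_iter=1000, burn_in=500, thin=5, retain_last=250)

    def test_unstandardized_phenotype_rejected(self):
        rng = np.random.default_rng(0)
        markers = _markers_from_array(rng.standard_normal((50, 4)))
        with pytest.raises(ValueError, match="standardized"):
            run_gibbs(rng.normal(5, 2, 50), markers)

    def test_unstandardized_markers_rejected(self):
        rng = np.random.default_rng(0)
        man = pd.DataFrame(
            {"id": ["a"], "chr": ["1"], "pos": [1], "set": ["methylation"]}
        )
        mm = MarkerMatrix(pd.DataFrame({"a": rng.normal(3, 2, 50)}), man)
        with pytest.raises(ValueError, match="standardized"):
            run_gibbs(_std(rng.standard_normal(50)), mm)


class TestOracle:
    def test_spike_only_prior_gives_zero_pip(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((50, 1))
        y = _std(rng.standard_normal(50))
        with np.errstate(divide="ignore"):
            pips, _ = enumerate_posterior_oracle(
                y, x, (0.01, 0.1, 1.0), 1.0, 1.0, (1.0, 0.0, 0.0, 0.0)
            )
        assert pips[0] == 0.0

    def test_orthogonal_markers_factorize(self):
        n = 64
        x = np.zeros((n, 2))
        x[: n // 2, 0] = 1.0
        x[n // 2 :, 0] = -1.0
        x[:, 1] = np.tile([1.0, -1.0], n // 2)
        rng = np.random.default_rng(2)
        y = _std(0.4 * x[:, 0] + rng.standard_normal(n))
        pips, config_post = enumerate_posterior_oracle(
            y, x, (0.01, 0.1, 1.0), 1.0, 0.8, (0.4, 0.2, 0.2, 0.2)
        )
        # joint posterior equals the product of per-marker marginals
        marg0 = {c: 0.0 for c in range(4)}
        marg1 = {c: 0.0 for c in range(4)}
        for (c0, c1), prob in config_post.items():
            marg0[c0] += prob
            marg1[c1] += prob
        for (c0, c1), prob in config_post.items():
            assert prob == pytest.approx(marg0[c0] * marg1[c1], abs=1e-10)

    def test_refuses_large_p(self):
        with pytest.raises(ValueError, match="p <= 8"):
            enumerate_posterior_oracle(
                np.zeros(10), np.zeros((10, 9)), (0.1, 0.2, 0.3), 1, 1, (0.7, 0.1, 0.1, 0.1)
            )

    def test_gibbs_matches_enumeration(self):
        """Fixed-hyperparameter Gibbs PIPs agree with exact enumeration."""
        rng = np.random.default_rng(7)
        n, p = 200, 5
        markers = _markers_from_array(rng.standard_normal((n, p)))
        z = markers.values.to_numpy()
        y = _std(z @ np.array([0.3, 0.2, 0.1, 0.0, 0.0]) + rng.standard_normal(n))
        gamma, sg, se = (0.001, 0.01, 0.1), 1.0, 0.8
        pi = np.array([0.7, 0.1, 0.1, 0.1])
        exact, _ = enumerate_posterior_oracle(y, z, gamma, sg, se, pi)
        config = GibbsConfig(
            n_iter=12_000, burn_in=2_000, thin=2, n_chains=1, retain_last=5_000, seed=5
        )
        draws = run_gibbs(
            y,
            markers,
            spec=MixtureSpec(gamma={"methylation": gamma}),
            config=config,
            fix_hyperparameters={"sigma2_g": [sg], "sigma2_e": se, "pi": pi},
        )
        got = summaries.marker_pips(draws).to_numpy()
        assert np.abs(got - exact).max() < 0.03


class TestSamplerBehaviour:
    def test_null_data_low_variance_explained(self):
        rng = np.random.default_rng(3)
        markers = _markers_from_array(rng.standard_normal((500, 200)))
        y = _std(rng.standard_normal(500))
        config = GibbsConfig(n_iter=800, burn_in=300, thin=2, n_chains=2, retain_last=200, seed=1)
        draws = run_gibbs(y, markers, config=config)
        part = summaries.variance_partition(draws)["methylation"]
        assert part.mean < 0.05

    def test_strong_signal_recovered(self):
        rng = np.random.default_rng(4)
        n, p = 1000, 100
        markers = _markers_from_array(rng.standard_normal((n, p)))
        z = markers.values.to_numpy()
        beta = np.zeros(p)
        beta[7] = np.sqrt(0.10)
        y = _std(z @ beta + np.sqrt(0.9) * rng.standard_normal(n))
        config = GibbsConfig(n_iter=800, burn_in=300, thin=2, n_chains=2, retain_last=200, seed=2)
        draws = run_gibbs(y, markers, config=config)
        pips = summaries.marker_pips(draws)
        assert pips.iloc[7] > 0.95

    def test_duplicate_columns_share_inclusion(self):
        rng = np.random.default_rng(5)
        n, p = 800, 50
        x = rng.standard_normal((n, p))
        x[:, 1] = x[:, 0]  # exact duplicate of a causal marker
        markers = _markers_from_array(x)
        z = markers.values.to_numpy()
        y = _std(z[:, 0] * np.sqrt(0.1) + np.sqrt(0.9) * rng.standard_normal(n))
        config = GibbsConfig(n_iter=1000, burn_in=400, thin=2, n_chains=2, retain_last=250, seed=3)
        draws = run_gibbs(y, markers, config=config)
        incl = draws.components != 0
        union = incl[:, [0, 1]].any(axis=1).mean()
        pips = summaries.marker_pips(draws)
        assert union > 0.95
        assert pips.iloc[0] < 0.95 and pips.iloc[1] < 0.95  # split between duplicates

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        n, p = 300, 20
        x = rng.standard_normal((n, p))
        markers = _markers_from_array(x)
        z = markers.values.to_numpy()
        y = _std(z[:, 3] * 0.4 + rng.standard_normal(n))
        config = GibbsConfig(
            n_iter=6000, burn_in=1000, thin=2, n_chains=2, retain_last=2500, seed=4
        )
        fixed = {"sigma2_g": [1.0], "sigma2_e": 0.8, "pi": [0.7, 0.1, 0.1, 0.1]}
        pips_a = summaries.marker_pips(
            run_gibbs(y, markers, config=config, fix_hyperparameters=fixed)
        )
        perm = rng.permutation(p)
        man_p = markers.manifest.iloc[perm].reset_index(drop=True)
        markers_p = MarkerMatrix(markers.values.iloc[:, perm], man_p, standardized=True)
        pips_b = summaries.marker_pips(
            run_gibbs(y, markers_p, config=config, fix_hyperparameters=fixed)
        )
        # same identifiers recover statistically identical inclusion rates
        joined = pd.concat([pips_a.rename("a"), pips_b.rename("b")], axis=1)
        assert (joined["a"] - joined["b"]).abs().max() < 0.05

    def test_prior_recovery_under_no_information(self):
        rng = np.random.default_rng(8)
        markers = _markers_from_array(rng.standard_normal((12, 3)))
        y = _std(rng.standard_normal(12))
        config = GibbsConfig(n_iter=3000, burn_in=1000, thin=2, n_chains=2, retain_last=500, seed=5)
        draws = run_gibbs(y, markers, config=config)
        pi_mean = draws.pi.mean(axis=0)[0]
        # Dirichlet(1,1,1,1) prior mean is 0.25 per component; p=3 markers
        # contribute little likelihood information
        assert np.all(np.abs(pi_mean - 0.25) < 0.2)

    def test_two_set_analysis_runs_and_partitions(self, small_cohort):
        config, observed, pheno, truth = small_cohort
        covs = pheno[["age", "sex", "smoking", "bmi"]].copy()
        covs["batch"] = pheno["batch"].astype(str)
        resid = preprocess.residualize(observed.values, covs)
        both = preprocess.standardize(
            MarkerMatrix(resid, observed.manifest.copy(), standardized=False)
        )
        epi = both.subset_set("methylation")
        gen = both.subset_set("genotype")
        y = preprocess.standardize_vector(
            preprocess.residualize(truth.latent_g, covs)
        ).to_numpy()
        gc = GibbsConfig(n_iter=600, burn_in=200, thin=2, n_chains=2, retain_last=150, seed=6)
        draws = run_gibbs(y, [epi, gen], config=gc)
        parts = summaries.variance_partition(draws)
        assert set(parts) == {"methylation", "genotype"}
        assert 0 <= parts["methylation"].mean <= 1
        assert draws.n_draws == 300


class TestConvergenceDiagnostics:
    def test_identical_chains_rhat_one(self):
        beta = np.tile(np.array([[0.1, 0.0]]), (8, 1))  # constant trace
        comp = (beta != 0).astype(np.int8)
        draws = make_draws(beta, comp, chains=2)
        diag = convergence_diagnostics(draws)
        assert diag["var_explained[methylation]"]["rhat"] == pytest.approx(1.0)
        assert not diag["var_explained[methylation]"]["flag"]

    def test_separated_chains_flagged(self):
        n = 40
        beta = np.zeros((2 * n, 2))
        beta[:n, 0] = 0.1
        beta[n:, 0] = 0.9
        comp = (beta != 0).astype(np.int8)
        draws = make_draws(beta, comp, chains=2)
        diag = convergence_diagnostics(draws)
        assert diag["var_explained[methylation]"]["rhat"] > 1.1
        assert diag["var_explained[methylation]"]["flag"]

    def test_single_chain_is_error(self):
        beta = np.array([[0.1], [0.2]])
        draws = make_draws(beta, (beta != 0).astype(np.int8), chains=1)
        with pytest.raises(ValueError, match="two chains"):
            convergence_diagnostics(draws)

    def test_well_mixed_sampler_passes(self):
        rng = np.random.default_rng(9)
        markers = _markers_from_array(rng.standard_normal((200, 20)))
        y = _std(rng.standard_normal(200))
        config = GibbsConfig(n_iter=2000, burn_in=500, thin=3, n_chains=2, retain_last=500, seed=7)
        draws = run_gibbs(y, markers, config=config)
        diag = convergence_diagnostics(draws)
        assert all(d["rhat"] < 1.1 for d in diag.values())


def test_cell_composition_confounding_does_not_shift_partition():
    """Latent cell factors loading on a fifth of CpGs leave the variance
    share within the posterior interval width of the clean estimate."""
    from epivar import sim

    base_kw = dict(
        n_samples=800,
        n_cpg=600,
        n_snp=0,
        target_var_epi=0.4,
        target_var_gen=0.0,
        seed=21,
    )
    shares = {}
    for label, cell_sd in (("clean", 0.0), ("confounded", 0.4)):
        config = sim.SimulationConfig(
            confounders=sim.ConfounderSpec(batch_marker_sd=0.0, cell_marker_sd=cell_sd),
            **base_kw,
        )
        observed, pheno, truth = sim.simulate_cohort(config)
        covs = pheno[["age", "sex", "smoking", "bmi"]]
        resid = preprocess.residualize(observed.values, covs)
        markers = preprocess.standardize(
            MarkerMatrix(resid, observed.manifest.copy(), standardized=False)
        )
        y = preprocess.standardize_vector(
            preprocess.residualize(truth.latent_g, covs)
        ).to_numpy()
        gc = GibbsConfig(n_iter=800, burn_in=300, thin=2, n_chains=2, retain_last=200, seed=22)
        part = summaries.variance_partition(run_gibbs(y, markers, config=gc))["methylation"]
        shares[label] = part
    width = shares["clean"].ci_high - shares["clean"].ci_low
    assert abs(shares["clean"].mean - shares["confounded"].mean) < width
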