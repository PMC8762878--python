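import numpy as np
import pandas as pd
import pytest

from epivar import preprocess, sim
from epivar.containers import MarkerMatrix, PosteriorDraws


@pytest.fixture(scope="session")
def small_cohort():
    """A small full cohort: markers, phenotypes, truth."""
    config = sim.SimulationConfig(
        n_samples=400, n_cpg=300, n_snp=100, seed=7, target_var_epi=0.4, target_var_gen=0.2
    )
    observed, pheno, truth = sim.simulate_cohort(config)
    return config, observed, pheno, truth


@pytest.fixture()
def marker_matrix():
    rng = np.random.default_rng(3)
    n, p = 50, 8
    man = pd.DataFrame(
        {
            "id": [f"m{j}" for j in range(p)],
            "chr": ["1"] * (p - 2) + ["X", "2"],
            "pos": np.arange(p) * 1000 + 100,
            "set": ["methylation"] * (p - 3) + ["genotype"] * 3,
        }
    )
    vals = pd.DataFrame(
        rng.standard_normal((n, p)),
        index=[f"S{i}" for i in range(n)],
        columns=man["id"],
    )
    vals.iloc[:, p - 3 :] = rng.binomial(2, 0.3, (n, 3))
    return MarkerMatrix(vals, man)


def make_draws(beta, components, set_index=None, set_labels=None, chains=1):
    """Hand-built PosteriorDraws for summary-level tests."""
    beta = np.asarray(beta, dtype=float)
    components = np.asarray(components, dtype=np.int8)
    n_draws, p = beta.shape
    set_index = (
        np.zeros(p, dtype=np.int64) if set_index is None else np.asarray(set_index)
    )
    set_labels = set_labels or ["methylation"]
    n_sets = len(set_labels)
    return PosteriorDraws(
        beta=beta,
        components=components,
        sigma2_g=np.full((n_draws, n_sets), 0.5),
        sigma2_e=np.full(n_draws, 0.5),
        pi=np.full((n_draws, n_sets, 4), 0.25),
        chain=np.repeat(np.arange(chains), n_draws // chains),
        marker_ids=[f"m{j}" for j in range(p)],
        set_labels=set_labels,
        set_index=set_index,
    )


@pytest.fixture()
def standardized_small(marker_matrix):
    keep = marker_matrix.manifest["chr"] != "X"
    mm = marker_matrix.subset_markers(marker_matrix.manifest.loc[keep, "id"])
    return preprocess.standardize(mm)
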