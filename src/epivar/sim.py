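"""Synthetic cohort generator.

Produces sample x marker matrices (continuous methylation-like values in
correlated genomic blocks, and SNP dosages under Hardy-Weinberg), a sparse
mixture causal architecture over both marker sets, covariate and batch
confounding, latent cell-composition factors, and a multi-test cognitive
battery loading on a latent general factor.  Every stage records ground
truth so downstream estimators can be validated without external data.

The generator emulates the statistical structure of a blood-methylation
study of general cognitive ability: a phenotype with a large methylation
variance component (default 0.416) and a SNP component (default 0.379),
per-marker effect variances drawn from a spike plus three Gaussian
mixtures, and CpGs arranged so that within-block neighbours are < 2.5 kb
apart while distinct blocks are farther apart than that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MarkerMatrix

# per-marker variance fractions of the mixture components, smallest first
GAMMA_EPI = (0.0001, 0.001, 0.01)
GAMMA_GEN = (0.00001, 0.0001, 0.001)

_WITHIN_BLOCK_BP = 500
_BETWEEN_BLOCK_BP = 10_000
_SNP_SPACING_BP = 5_000


@dataclass
class ConfounderSpec:
    """Effect sizes of covariates and technical factors.

    Phenotype effects are in SD of the latent trait per SD of the
    (standardized) covariate.  Marker effects are the SD of the per-marker
    perturbation added to raw marker values.
    """

    age_pheno: float = -0.25
    sex_pheno: float = 0.05
    bmi_pheno: float = -0.10
    smoking_pheno: float = -0.15
    batch_marker_sd: float = 0.2
    cell_marker_sd: float = 0.3
    cell_cpg_fraction: float = 0.2   # fraction of CpGs loaded by each cell factor
    cell_pheno: float = 0.0          # cell factors are technical by default
    n_cell_factors: int = 2

    def pheno_var(self) -> float:
        return (
            self.age_pheno**2
            + self.sex_pheno**2
            + self.bmi_pheno**2
            + self.smoking_pheno**2
            + self.n_cell_factors * self.cell_pheno**2
        )


@dataclass
class SimulationConfig:
    n_samples: int = 1000
    n_cpg: int = 2000
    n_snp: int = 500
    block_size: int = 5
    block_rho: float = 0.6
    maf_range: tuple = (0.01, 0.5)
    # spike, small, medium, large occupancy per marker set
    mixture_fractions_epi: tuple = (0.95, 0.04, 0.008, 0.002)
    mixture_fractions_gen: tuple = (0.95, 0.04, 0.008, 0.002)
    target_var_epi: float = 0.416
    target_var_gen: float = 0.379
    epi_gen_overlap: float = 0.0  # share of causal-CpG signal driven by the SNP genetic value
    confounders: ConfounderSpec = field(default_factory=ConfounderSpec)
    battery_loadings: tuple = (0.8, 0.7, 0.7, 0.6)
    battery_noise_sd: tuple | None = None  # default sqrt(1 - loading^2)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.block_size) < 1 or self.n_cpg < 0 or self.n_snp < 0:
            raise ValueError("non-positive simulation dimensions")
        if not (0 <= self.block_rho < 1):
            raise ValueError("block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for frac in (self.mixture_fractions_epi, self.mixture_fractions_gen):
            if len(frac) != 4 or any(f < 0 for f in frac):
                raise ValueError("mixture fractions are 4 non-negative numbers")
            if abs(sum(frac) - 1.0) > 1e-9:
                raise ValueError("mixture fractions must sum to 1")
        total = self.target_var_epi + self.target_var_gen + self.confounders.pheno_var()
        if not (0 <= self.target_var_epi < 1 and 0 <= self.target_var_gen < 1):
            raise ValueError("target variance shares must lie in [0, 1)")
        if total > 1:
            raise ValueError(
                f"variance budget exceeded: epi + gen + covariate shares = {total:.3f} > 1"
            )
        if self.battery_noise_sd is None:
            self.battery_noise_sd = tuple(
                float(np.sqrt(max(1.0 - l**2, 0.0))) for l in self.battery_loadings
            )
        if len(self.battery_noise_sd) != len(self.battery_loadings):
            raise ValueError("battery_noise_sd length must match battery_loadings")


@dataclass
class SyntheticTruth:
    causal_ids: dict                 # set label -> list of marker ids
    true_effects: pd.Series          # per-marker standardized effect (0 if non-causal)
    component_assignment: pd.Series  # per-marker int in {0,1,2,3}
    realized_var_epi: float = np.nan
    realized_var_gen: float = np.nan
    latent_g: pd.Series | None = None
    genetic_values: dict | None = None  # set label -> per-sample linear predictor


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stage)))


def _standardize_cols(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _cpg_manifest(n_cpg: int, block_size: int) -> pd.DataFrame:
    """Deterministic positions: 500 bp within blocks, 10 kb between."""
    ids, chrs, pos = [], [], []
    n_blocks = int(np.ceil(n_cpg / block_size))
    cursor = {c: 1_000_000 for c in range(1, 23)}
    for b in range(n_blocks):
        c = (b % 22) + 1
        start = cursor[c]
        size = min(block_size, n_cpg - b * block_size)
        for j in range(size):
            ids.append(f"cg{b * block_size + j:07d}")
            chrs.append(str(c))
            pos.append(start + j * _WITHIN_BLOCK_BP)
        cursor[c] = start + (size - 1) * _WITHIN_BLOCK_BP + _BETWEEN_BLOCK_BP
    return pd.DataFrame({"id": ids, "chr": chrs, "pos": pos, "set": "methylation"})


def _snp_manifest(n_snp: int) -> pd.DataFrame:
    ids = [f"rs{j:07d}" for j in range(n_snp)]
    chrs = [str((j % 22) + 1) for j in range(n_snp)]
    pos = [50_000_000 + (j // 22) * _SNP_SPACING_BP for j in range(n_snp)]
    return pd.DataFrame({"id": ids, "chr": chrs, "pos": pos, "set": "genotype"})


def simulate_markers(config: SimulationConfig) -> MarkerMatrix:
    """Draw raw marker values: blocked CpGs and Hardy-Weinberg dosages.

    CpG blocks use an exchangeable one-factor construction: each value is
    sqrt(rho) * shared-block factor + sqrt(1-rho) * unique noise, giving a
    within-block pairwise correlation of ``block_rho`` at O(n*p) cost.
    """
    rng = _rng(config, 0)
    n, rho = config.n_samples, config.block_rho
    manifest = pd.concat(
        [_cpg_manifest(config.n_cpg, config.block_size), _snp_manifest(config.n_snp)],
        ignore_index=True,
    )

    n_blocks = int(np.ceil(config.n_cpg / config.block_size))
    shared = rng.standard_normal((n, n_blocks))
    cpg = np.empty((n, config.n_cpg))
    for j in range(config.n_cpg):
        b = j // config.block_size
        cpg[:, j] = np.sqrt(rho) * shared[:, b] + np.sqrt(1 - rho) * rng.standard_normal(n)

    maf = rng.uniform(*config.maf_range, size=config.n_snp)
    snp = rng.binomial(2, maf, size=(n, config.n_snp)).astype(float)

    values = pd.DataFrame(
        np.hstack([cpg, snp]),
        index=pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id"),
        columns=manifest["id"],
    )
    return MarkerMatrix(values, manifest, standardized=False)


def assign_architecture(markers: MarkerMatrix, config: SimulationConfig) -> SyntheticTruth:
    """Assign mixture components and standardized effects to markers.

    Causal effects are drawn from N(0, gamma_k) for each marker's mixture
    component, then rescaled per set so the empirical variance of the
    standardized linear predictor equals the target share exactly.
    """
    rng = _rng(config, 1)
    manifest = markers.manifest
    effects = pd.Series(0.0, index=manifest["id"])
    components = pd.Series(0, index=manifest["id"], dtype=int)
    causal_ids: dict = {}
    genetic_values: dict = {}

    plan = [
        ("methylation", config.mixture_fractions_epi, GAMMA_EPI, config.target_var_epi),
        ("genotype", config.mixture_fractions_gen, GAMMA_GEN, config.target_var_gen),
    ]
    for set_label, fractions, gammas, target in plan:
        ids = manifest.loc[manifest["set"] == set_label, "id"].to_numpy()
        if ids.size == 0:
            if target > 0:
                raise ValueError(f"target variance for empty marker set {set_label!r}")
            causal_ids[set_label] = []
            continue
        comp = rng.choice(4, size=ids.size, p=np.asarray(fractions))
        if target > 0 and not np.any(comp > 0):
            raise ValueError(
                f"all-null architecture for set {set_label!r} with positive target variance"
            )
        beta = np.zeros(ids.size)
        for k in (1, 2, 3):
            mask = comp == k
            beta[mask] = rng.normal(0.0, np.sqrt(gammas[k - 1]), size=mask.sum())
        z = _standardize_cols(markers.values[ids].to_numpy(float))
        g = z @ beta
        realized = g.var()
        if target > 0:
            if realized == 0:  # drawn effects all exactly zero
                raise ValueError(f"degenerate zero effects for set {set_label!r}")
            beta *= np.sqrt(target / realized)
            g = z @ beta
        components.loc[ids] = comp
        effects.loc[ids] = beta
        causal_ids[set_label] = list(ids[comp > 0])
        genetic_values[set_label] = pd.Series(g, index=markers.values.index)

    return SyntheticTruth(
        causal_ids=causal_ids,
        true_effects=effects,
        component_assignment=components,
        genetic_values=genetic_values,
    )


def simulate_phenotypes(
    markers: MarkerMatrix, truth: SyntheticTruth, config: SimulationConfig
):
    """Build covariates, the latent trait and the cognitive battery.

    Returns ``(phenotypes, observed_markers, truth)``.  The latent trait is
    the sum of the per-set genetic values, covariate effects and Gaussian
    noise standardized so the trait has variance ~1.  Each battery test is
    loading * standardized(g) + unique noise.  ``observed_markers`` carries
    the batch and cell-composition perturbations the analyst would see;
    the genetic values were computed from the clean matrix, so these
    factors act as pure confounders.
    """
    if len(config.battery_loadings) < 1:
        raise ValueError("at least one battery test required")
    rng = _rng(config, 2)
    cf = config.confounders
    n = markers.n_samples
    idx = markers.values.index

    age = rng.normal(50.0, 13.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    bmi = rng.normal(27.0, 4.0, n)
    smoking = rng.standard_normal(n)
    batch = rng.integers(0, 2, n)
    cells = rng.standard_normal((n, cf.n_cell_factors))

    cov_effect = (
        cf.age_pheno * _standardize_cols(age[:, None])[:, 0]
        + cf.sex_pheno * _standardize_cols(sex[:, None])[:, 0]
        + cf.bmi_pheno * _standardize_cols(bmi[:, None])[:, 0]
        + cf.smoking_pheno * _standardize_cols(smoking[:, None])[:, 0]
        + cf.cell_pheno * cells.sum(axis=1)
    )

    g_epi = truth.genetic_values.get("methylation", pd.Series(0.0, index=idx)).to_numpy()
    g_gen = truth.genetic_values.get("genotype", pd.Series(0.0, index=idx)).to_numpy()
    noise_var = max(1.0 - g_epi.var() - g_gen.var() - cf.pheno_var(), 1e-6)
    noise = rng.standard_normal(n)
    noise = (noise - noise.mean()) / noise.std() * np.sqrt(noise_var)

    g = g_epi + g_gen + cov_effect + noise
    g_std = (g - g.mean()) / g.std()

    tests = {}
    for t, (loading, nsd) in enumerate(zip(config.battery_loadings, config.battery_noise_sd)):
        tests[f"test_{t + 1}"] = loading * g_std + nsd * rng.standard_normal(n)

    pheno = pd.DataFrame(
        {
            **tests,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "smoking": smoking,
            "batch": batch,
            **{f"cell_{c + 1}": cells[:, c] for c in range(cf.n_cell_factors)},
        },
        index=idx,
    )

    # technical perturbation of the observed methylation values
    observed = markers.values.to_numpy(float).copy()
    cpg_cols = np.flatnonzero((markers.manifest["set"] == "methylation").to_numpy())
    if cpg_cols.size:
        if cf.batch_marker_sd > 0:
            shift = rng.normal(0.0, cf.batch_marker_sd, cpg_cols.size)
            observed[:, cpg_cols] += np.outer(batch.astype(float), shift)
        if cf.cell_marker_sd > 0 and cf.cell_cpg_fraction > 0:
            for c in range(cf.n_cell_factors):
                m = max(1, int(round(cf.cell_cpg_fraction * cpg_cols.size)))
                loaded = rng.choice(cpg_cols, size=m, replace=False)
                loads = rng.normal(0.0, cf.cell_marker_sd, m)
                observed[:, loaded] += np.outer(cells[:, c], loads)
    if config.epi_gen_overlap > 0 and cpg_cols.size and g_gen.std() > 0:
        causal_cpg = [c for c in truth.causal_ids.get("methylation", [])]
        cols = [markers.values.columns.get_loc(c) for c in causal_cpg]
        u = (g_gen - g_gen.mean()) / g_gen.std()
        observed[:, cols] += np.sqrt(config.epi_gen_overlap) * u[:, None]

    observed_markers = MarkerMatrix(
        pd.DataFrame(observed, index=idx, columns=markers.values.columns),
        markers.manifest.copy(),
        standardized=False,
    )

    var_g = g.var()
    truth.realized_var_epi = float(g_epi.var() / var_g)
    truth.realized_var_gen = float(g_gen.var() / var_g)
    truth.latent_g = pd.Series(g, index=idx, name="latent_g")
    return pheno, observed_markers, truth


def simulate_cohort(config: SimulationConfig):
    """Run the full generator: markers, architecture, phenotypes."""
    markers = simulate_markers(config)
    truth = assign_architecture(markers, config)
    pheno, observed, truth = simulate_phenotypes(markers, truth, config)
    return observed, pheno, truth


def inject_missing(markers: MarkerMatrix, rate: float, seed: int = 0) -> MarkerMatrix:
    """Set a random subset of entries missing; others are untouched."""
    if not (0 <= rate < 1):
        raise ValueError("missingness rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    vals = markers.values.to_numpy(float).copy()
    mask = rng.random(vals.shape) < rate
    vals[mask] = np.nan
    return MarkerMatrix(
        pd.DataFrame(vals, index=markers.values.index, columns=markers.values.columns),
        markers.manifest.copy(),
        markers.standardized,
    )


def write_cohort(out_dir, markers: MarkerMatrix, pheno: pd.DataFrame, truth: SyntheticTruth) -> None:
    """Write the cohort as delimited text plus a key-value truth record."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    markers.values.to_csv(out / "markers.tsv", sep="\t")
    markers.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    pheno.to_csv(out / "phenotypes.tsv", sep="\t")
    with open(out / "truth.txt", "w") as fh:
        fh.write(f"realized_var_epi\t{truth.realized_var_epi:.10f}\n")
        fh.write(f"realized_var_gen\t{truth.realized_var_gen:.10f}\n")
        for set_label, ids in truth.causal_ids.items():
            fh.write(f"causal_{set_label}\t{','.join(ids)}\n")
    effects = pd.DataFrame(
        {"effect": truth.true_effects, "component": truth.component_assignment}
    )
    effects.to_csv(out / "true_effects.tsv", sep="\t", index_label="id")
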