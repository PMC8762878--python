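"""Downstream association suites for scores and measured traits.

Age- and sex-adjusted linear regressions of a predictor (an EpiScore or a
measured trait) against risk-factor outcomes and protein panels, with the
transformation rules used in cognitive-ageing cohort analyses: log
transforms for skewed outcomes (log(x+1) for alcohol units), rank-based
inverse normal transforms (Blom offsets) for protein levels, Bonferroni
control over a panel, and concordance summaries comparing two predictors'
effect-size vectors.

Predictor and outcome are standardized before fitting by default, so the
estimates are per-SD and comparable across outcomes and panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import residualize


@dataclass
class AssociationResult:
    predictor: str
    outcome: str
    estimate: float
    se: float
    p: float
    n: int
    significant: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1):
            raise ValueError("p-value out of range")


def inverse_normal_transform(values: pd.Series) -> pd.Series:
    """Rank-based inverse normal transform with Blom offsets.

    Maps average ranks through Phi^{-1}((rank - 3/8) / (n + 1/4)); ties
    share the average rank.  Missing entries stay missing.
    """
    x = values.to_numpy(float)
    mask = ~np.isnan(x)
    obs = x[mask]
    if np.unique(obs).size < 2:
        raise ValueError("inverse normal transform needs at least two distinct values")
    ranks = stats.rankdata(obs, method="average")
    out = np.full_like(x, np.nan)
    out[mask] = stats.norm.ppf((ranks - 0.375) / (obs.size + 0.25))
    return pd.Series(out, index=values.index, name=values.name)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _single_ols(y: np.ndarray, pred: np.ndarray, covs: np.ndarray):
    """Slope, SE and p of pred in y ~ pred + covs + intercept."""
    x = np.column_stack([np.ones_like(pred), pred, covs])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = len(y) - x.shape[1]
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), dof)
    return float(beta[1]), float(se), float(p)


def _apply_transform(x: pd.Series, how: str | None) -> pd.Series:
    if how is None:
        return x
    if how == "log":
        if (x.dropna() <= 0).any():
            raise ValueError(f"non-positive values under log transform for {x.name!r}")
        return np.log(x)
    if how == "log1p":
        return np.log1p(x)
    raise ValueError(f"unknown transform {how!r}")


def risk_factor_assoc(
    scores: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    transforms: dict | None = None,
    reverse_code: list | None = None,
    standardized: bool = True,
) -> list[AssociationResult]:
    """One covariate-adjusted regression per (predictor, outcome) pair.

    ``transforms`` maps outcome name to ``"log"`` or ``"log1p"``;
    ``reverse_code`` lists outcomes whose sign is flipped so that higher
    values are the favourable direction.
    """
    transforms = transforms or {}
    reverse = set(reverse_code or [])
    results = []
    for out_col in outcomes.columns:
        y_raw = _apply_transform(outcomes[out_col], transforms.get(out_col))
        if out_col in reverse:
            y_raw = -y_raw
        for pred_col in scores.columns:
            df = pd.concat(
                [y_raw.rename("_y"), scores[pred_col].rename("_x"), covariates], axis=1
            ).dropna()
            y = df["_y"].to_numpy(float)
            x = df["_x"].to_numpy(float)
            if standardized:
                y, x = _zscore(y), _zscore(x)
            est, se, p = _single_ols(y, x, df[covariates.columns].to_numpy(float))
            results.append(
                AssociationResult(
                    predictor=pred_col, outcome=out_col, estimate=est, se=se, p=p, n=len(df)
                )
            )
    return results


def protein_assoc(
    scores: pd.DataFrame,
    proteins: pd.DataFrame,
    covariates: pd.DataFrame,
    bonferroni_m: int | None = None,
    pre_adjust: bool = True,
) -> dict:
    """Panel-wide associations with Bonferroni control and concordance.

    Each protein is inverse-normal transformed and residualized on the
    covariates (when ``pre_adjust``), then regressed on each predictor
    with the covariates in the model.  Returns per-predictor results,
    significant counts at p < 0.05/m, the overlap of significant sets,
    and the Pearson correlation between the two predictors' effect-size
    vectors (when exactly two predictors are given).
    """
    m = bonferroni_m if bonferroni_m is not None else proteins.shape[1]
    if m != proteins.shape[1]:
        raise ValueError(
            f"Bonferroni m = {m} does not match panel size {proteins.shape[1]}"
        )
    threshold = 0.05 / m
    panel = proteins.copy()
    for col in panel.columns:
        panel[col] = inverse_normal_transform(panel[col])
    if pre_adjust:
        complete = panel.dropna()
        panel = residualize(complete, covariates.loc[complete.index])
    results = {pred: [] for pred in scores.columns}
    for col in panel.columns:
        for pred in scores.columns:
            df = pd.concat(
                [panel[col].rename("_y"), scores[pred].rename("_x"), covariates], axis=1
            ).dropna()
            y, x = _zscore(df["_y"].to_numpy(float)), _zscore(df["_x"].to_numpy(float))
            est, se, p = _single_ols(y, x, df[covariates.columns].to_numpy(float))
            results[pred].append(
                AssociationResult(
                    predictor=pred,
                    outcome=col,
                    estimate=est,
                    se=se,
                    p=p,
                    n=len(df),
                    significant=p < threshold,
                )
            )
    sig_sets = {
        pred: {r.outcome for r in res if r.significant} for pred, res in results.items()
    }
    out = {
        "results": results,
        "threshold": threshold,
        "significant_counts": {pred: len(s) for pred, s in sig_sets.items()},
    }
    preds = list(scores.columns)
    if len(preds) == 2:
        out["overlap"] = sorted(sig_sets[preds[0]] & sig_sets[preds[1]])
        a = np.array([r.estimate for r in results[preds[0]]])
        b = np.array([r.estimate for r in results[preds[1]]])
        out["effect_correlation"] = float(np.corrcoef(a, b)[0, 1])
    return out


def effect_concordance(results_a: list, results_b: list) -> dict:
    """Correlation and regression of matched effect-size vectors.

    Matches results by outcome label, computes the Pearson r of the
    paired estimates and the OLS slope of b on a with its 95% CI (the
    attenuation direction of a noisier proxy shows up as slope < 1).
    """
    by_outcome_a = {r.outcome: r.estimate for r in results_a}
    pairs = [
        (by_outcome_a[r.outcome], r.estimate) for r in results_b if r.outcome in by_outcome_a
    ]
    if len(pairs) < 3:
        raise ValueError("need at least three matched outcomes for concordance")
    a, b = map(np.asarray, zip(*pairs))
    r = float(np.corrcoef(a, b)[0, 1])
    fit = stats.linregress(a, b)
    dof = len(pairs) - 2
    half = stats.t.ppf(0.975, dof) * fit.stderr
    return {
        "r": r,
        "slope": float(fit.slope),
        "slope_ci": (float(fit.slope - half), float(fit.slope + half)),
        "n": len(pairs),
    }
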