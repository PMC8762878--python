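"""Epigenetic and polygenic score construction and evaluation.

An EpiScore is a per-person weighted sum of standardized methylation
values, the weights being the mean posterior effect sizes from the
mixture-regression EWAS (zero draws included in the mean, so weights are
shrunk by inclusion frequency).  The module also provides incremental-R2
evaluation of a score over a covariate baseline and the closed-form
expected prediction R2 as a function of training sample size:

    E[R2] = N h2 / (N h2 + M)

for a training sample of N individuals, M markers affecting the trait
and a marker-captured variance proportion h2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MarkerMatrix, PosteriorDraws


@dataclass
class EpiScoreWeights:
    weights: pd.Series  # marker id -> mean posterior effect
    training_n: int
    set_label: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.weights.index.duplicated().any():
            raise ValueError("duplicate marker ids in weights")
        if not np.isfinite(self.weights.to_numpy(float)).all():
            raise ValueError("weights must be finite")


@dataclass
class PredictionSpec:
    n_training: int
    m_markers: int
    h2: float

    def __post_init__(self) -> None:
        if self.n_training <= 0 or self.m_markers <= 0:
            raise ValueError("N and M must be positive")
        if not (0 <= self.h2 <= 1):
            raise ValueError("h2 must lie in [0, 1]")


def extract_weights(
    draws: PosteriorDraws, set_label: str = "methylation", conditional: bool = False
) -> EpiScoreWeights:
    """Mean posterior effect per marker of one set.

    By default zeros (spike draws) are included in the mean; with
    ``conditional=True`` the mean is taken over inclusion draws only
    (markers never included get weight 0).
    """
    if draws.n_draws == 0:
        raise ValueError("no retained draws")
    cols = draws.markers_of_set(set_label)
    beta = draws.beta[:, cols]
    if conditional:
        incl = (draws.components[:, cols] != 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            w = np.where(incl > 0, beta.sum(axis=0) / np.maximum(incl, 1), 0.0)
    else:
        w = beta.mean(axis=0)
    ids = [draws.marker_ids[c] for c in cols]
    return EpiScoreWeights(
        weights=pd.Series(w, index=pd.Index(ids, name="id"), name="weight"),
        training_n=int(draws.meta.get("n_samples", -1)),
        set_label=set_label,
    )


def project_score(weights: EpiScoreWeights, target: MarkerMatrix) -> tuple[pd.Series, int]:
    """Project weights onto a target cohort.

    Each overlapping target column is scaled to mean 0, variance 1 within
    the target cohort; missing entries are then set to 0 (mean
    imputation on the standardized scale); the score is the weighted sum
    over available markers.  Returns ``(scores, n_overlap)``.
    """
    overlap = [m for m in weights.weights.index if m in target.values.columns]
    if not overlap:
        raise ValueError("no overlapping markers between weights and target")
    x = target.values[overlap].to_numpy(float)
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    z[np.isnan(z)] = 0.0
    w = weights.weights.loc[overlap].to_numpy(float)
    score = pd.Series(z @ w, index=target.values.index, name="score")
    return score, len(overlap)


def polygenic_score(weights: EpiScoreWeights, genotypes: MarkerMatrix) -> tuple[pd.Series, int]:
    """Weighted-sum score over dosages, with the same internal scaling."""
    return project_score(weights, genotypes)


def incremental_r2(
    outcome: pd.Series, baseline: pd.DataFrame, added: pd.DataFrame | pd.Series
) -> dict:
    """R2 gain and partial-F p-value of an added predictor block.

    Fits the baseline OLS model (with intercept) and the baseline plus the
    added block on complete cases; returns the ordinary (unadjusted) R2
    of both models, their difference, and the block F test.
    """
    if isinstance(added, pd.Series):
        added = added.to_frame()
    df = pd.concat([outcome.rename("_y"), baseline, added], axis=1).dropna()
    y = df["_y"].to_numpy(float)
    xb = np.column_stack([np.ones(len(df)), df[baseline.columns].to_numpy(float)])
    xf = np.column_stack([xb, df[added.columns].to_numpy(float)])
    if np.linalg.matrix_rank(xf) < xf.shape[1]:
        raise ValueError("rank-deficient design in incremental R2 model")

    def _rss_r2(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        rss = float(r @ r)
        tss = float(((y - y.mean()) ** 2).sum())
        return rss, 1.0 - rss / tss

    rss0, r2_0 = _rss_r2(xb)
    rss1, r2_1 = _rss_r2(xf)
    q = xf.shape[1] - xb.shape[1]
    dof = len(df) - xf.shape[1]
    f = ((rss0 - rss1) / q) / (rss1 / dof) if rss1 > 0 else np.inf
    p = float(stats.f.sf(f, q, dof))
    return {
        "r2_baseline": r2_0,
        "r2_full": r2_1,
        "delta_r2": r2_1 - r2_0,
        "f": float(f),
        "p": p,
        "n": len(df),
    }


def theoretical_r2(spec: PredictionSpec) -> float:
    """Expected out-of-sample prediction R2: N h2 / (N h2 + M)."""
    nh2 = spec.n_training * spec.h2
    if nh2 == 0:
        return 0.0
    return nh2 / (nh2 + spec.m_markers)


def prediction_curve(n_values, m_markers: int, h2: float) -> pd.DataFrame:
    """Expected R2 across training sample sizes."""
    rows = [
        {"n_training": int(n), "expected_r2": theoretical_r2(PredictionSpec(int(n), m_markers, h2))}
        for n in n_values
    ]
    return pd.DataFrame(rows)


def score_cellcount_check(score: pd.Series, cell_counts: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of a score with measured cell-count columns."""
    df = pd.concat([score.rename("_score"), cell_counts], axis=1).dropna()
    s = df["_score"].to_numpy(float)
    rows = []
    for col in cell_counts.columns:
        x = df[col].to_numpy(float)
        if np.std(s) == 0 or np.std(x) == 0:
            warnings.warn(f"constant input for {col!r}; correlation undefined")
            rows.append({"cell_type": col, "r": np.nan, "p": np.nan, "n": len(df)})
            continue
        r, p = stats.pearsonr(s, x)
        rows.append({"cell_type": col, "r": float(r), "p": float(p), "n": len(df)})
    return pd.DataFrame(rows)
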