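"""Phenotype derivation, covariate pre-correction and marker QC.

The analysis operates on pre-corrected, standardized data: cognitive test
scores have outliers beyond 3.5 SD removed, the general factor g is the
first unrotated principal component of the battery, phenotypes and marker
columns are residualized on their respective covariate lists by OLS, and
everything is scaled to mean 0, variance 1 (population convention, i.e.
divide by n) before entering the samplers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import AUTOSOMES, MarkerMatrix


def remove_outliers(scores: pd.DataFrame, k_sd: float = 3.5, columns=None) -> pd.DataFrame:
    """Set entries with |z| > k_sd to missing, column-wise.

    The mean and SD are computed once on the input column (population SD,
    non-missing entries); removal is a single pass, never re-iterated on
    the trimmed column.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    out = scores.copy()
    cols = list(columns) if columns is not None else list(scores.columns)
    for col in cols:
        x = out[col].to_numpy(float)
        sd = np.nanstd(x)
        if sd == 0:
            warnings.warn(f"column {col!r} is constant; no outliers removed")
            continue
        z = (x - np.nanmean(x)) / sd
        out.loc[np.abs(z) > k_sd, col] = np.nan
    return out


def derive_g(test_scores: pd.DataFrame):
    """First unrotated principal component of the standardized battery.

    Rows with any missing test are excluded.  The component sign is
    oriented so the first test column loads positively.  Returns
    ``(g, variance_share)`` where g is a Series over the complete rows.
    """
    if test_scores.shape[1] < 2:
        raise ValueError("need at least two test columns to derive g")
    complete = test_scores.dropna()
    x = complete.to_numpy(float)
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    g = u[:, 0] * s[0]  # scores on the first component
    if vt[0, 0] < 0:    # orient so the first test loads positively
        g = -g
    var_share = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(g, index=complete.index, name="g"), var_share


def _design(covariates: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Intercept + numeric covariates with categoricals expanded to dummies."""
    parts, names = [np.ones((len(covariates), 1))], ["intercept"]
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, prefix=col, drop_first=True)
            parts.append(d.to_numpy(float))
            names.extend(d.columns)
        else:
            parts.append(s.to_numpy(float)[:, None])
            names.append(col)
    return np.hstack(parts), names


def residualize(target, covariates: pd.DataFrame):
    """OLS residuals of each target column on the covariates.

    Raises on rank deficiency, naming the collinear design columns.
    Residuals are orthogonal to every covariate column.
    """
    squeeze = isinstance(target, pd.Series)
    tdf = target.to_frame() if squeeze else target
    x, names = _design(covariates.loc[tdf.index])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # pivoted QR flags the columns that add no rank
        from scipy.linalg import qr

        _, r, piv = qr(x, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    y = tdf.to_numpy(float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    out = pd.DataFrame(resid, index=tdf.index, columns=tdf.columns)
    return out.iloc[:, 0] if squeeze else out


def residualize_quadratic_age_check(
    phenotype: pd.Series, covariates: pd.DataFrame, age_col: str = "age"
) -> float:
    """Pearson r between residuals from linear-age vs linear+quadratic-age models."""
    if age_col not in covariates.columns:
        raise ValueError(f"covariates lack an {age_col!r} column")
    lin = residualize(phenotype, covariates)
    quad_cov = covariates.copy()
    quad_cov[f"{age_col}_sq"] = covariates[age_col].astype(float) ** 2
    quad = residualize(phenotype, quad_cov)
    return float(np.corrcoef(lin.to_numpy(float), quad.to_numpy(float))[0, 1])


def qc_filter(
    markers: MarkerMatrix,
    call_rate: float = 0.95,
    maf_min: float = 0.01,
    markers_first: bool = True,
):
    """Call-rate, autosome and MAF filtering.

    Drops markers (then samples, order configurable) whose non-missing
    fraction falls below ``call_rate``, markers on non-autosomal
    chromosomes, and genotype markers with minor allele frequency below
    ``maf_min``.  Returns the filtered matrix and a per-rule count report.
    """
    if not (0 <= call_rate <= 1 and 0 <= maf_min <= 0.5):
        raise ValueError("thresholds out of range")
    vals = markers.values
    man = markers.manifest.set_index("id")
    report = {}

    autosomal = man["chr"].astype(str).isin(AUTOSOMES)
    drop_auto = list(man.index[~autosomal])
    report["non_autosomal"] = len(drop_auto)
    vals = vals.drop(columns=drop_auto)
    man = man.drop(index=drop_auto)

    def _drop_low_markers(vals):
        cr = vals.notna().mean(axis=0)
        drop = list(cr.index[cr < call_rate])
        return vals.drop(columns=drop), drop

    def _drop_low_samples(vals):
        cr = vals.notna().mean(axis=1)
        drop = list(cr.index[cr < call_rate])
        return vals.drop(index=drop), drop

    if markers_first:
        vals, dropped_m = _drop_low_markers(vals)
        vals, dropped_s = _drop_low_samples(vals)
    else:
        vals, dropped_s = _drop_low_samples(vals)
        vals, dropped_m = _drop_low_markers(vals)
    report["low_callrate_markers"] = len(dropped_m)
    report["low_callrate_samples"] = len(dropped_s)
    man = man.drop(index=dropped_m)

    snp_ids = man.index[man["set"] == "genotype"]
    if len(snp_ids):
        freq = vals[snp_ids].mean(axis=0, skipna=True) / 2.0
        maf = np.minimum(freq, 1 - freq)
        drop_maf = list(maf.index[maf < maf_min])
    else:
        drop_maf = []
    report["low_maf"] = len(drop_maf)
    vals = vals.drop(columns=drop_maf)
    man = man.drop(index=drop_maf)

    if vals.shape[0] == 0 or vals.shape[1] == 0:
        raise ValueError("no data left after QC filtering")
    return MarkerMatrix(vals, man.reset_index(), markers.standardized), report


def standardize(markers: MarkerMatrix) -> MarkerMatrix:
    """Scale every column to mean 0, variance 1 (population convention).

    Missing entries stay missing; the moments are computed on non-missing
    entries.  Constant columns are an error (they cannot be scaled).
    """
    x = markers.values.to_numpy(float)
    sd = np.nanstd(x, axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        names = list(markers.values.columns[const])
        raise ValueError(f"constant columns cannot be standardized: {names}")
    z = (x - np.nanmean(x, axis=0)) / sd
    return MarkerMatrix(
        pd.DataFrame(z, index=markers.values.index, columns=markers.values.columns),
        markers.manifest.copy(),
        standardized=True,
    )


def standardize_vector(y: pd.Series) -> pd.Series:
    """Population-convention z-scoring of a phenotype vector."""
    x = y.to_numpy(float)
    sd = np.nanstd(x)
    if sd == 0:
        raise ValueError("constant phenotype")
    return pd.Series((x - np.nanmean(x)) / sd, index=y.index, name=y.name)
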