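"""Bayesian penalised regression with a spike plus Gaussian-mixture prior.

The model is the BayesR-style whole-genome regression

    y = sum_s X_s beta_s + e,    e ~ N(0, sigma2_e I)

where each marker effect in set s is a priori a mixture of a point mass
at zero and K Gaussians N(0, gamma_{s,k} * sigma2_G_s), with per-set
mixture proportions pi_s ~ Dirichlet(alpha) and scaled-inverse-chi^2
hyperpriors on sigma2_G_s and sigma2_e.  The gamma values are the
per-marker variance fractions (defaults 1e-4/1e-3/1e-2 for methylation,
1e-5/1e-4/1e-3 for genotypes).

A Gibbs sweep visits every marker in a fresh random permutation, samples
its mixture indicator from the marginal full conditional (effect
integrated out) and, if non-null, its effect from the conditional
Gaussian, maintaining the residual vector incrementally.  Variances and
proportions are then refreshed from their conjugate full conditionals.
An exhaustive-enumeration oracle over indicator configurations is
provided for small p as an independent correctness check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .containers import MarkerMatrix, PosteriorDraws

_K = 3  # non-null mixture components per set


@dataclass
class MixtureSpec:
    """Prior specification per marker set."""

    gamma: dict = field(
        default_factory=lambda: {
            "methylation": (0.0001, 0.001, 0.01),
            "genotype": (0.00001, 0.0001, 0.001),
        }
    )
    alpha: float = 1.0  # Dirichlet concentration, same for spike and slabs
    nu_g: float = 4.0
    s_g: float = 0.5  # scale of the sigma2_G hyperprior (phenotype variance units)
    nu_e: float = 4.0
    s_e: float = 0.5

    def __post_init__(self) -> None:
        for label, g in self.gamma.items():
            g = tuple(g)
            if len(g) != _K or any(x <= 0 for x in g) or any(
                g[i] >= g[i + 1] for i in range(_K - 1)
            ):
                raise ValueError(f"gamma for {label!r} must be {_K} strictly increasing positives")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class GibbsConfig:
    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    n_chains: int = 4
    retain_last: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be below n_iter")
        if (self.n_iter - self.burn_in) // self.thin < self.retain_last:
            raise ValueError("(n_iter - burn_in)/thin must cover retain_last draws")


@njit(cache=True)
def _chain(
    X,
    set_id,
    n_sets,
    y,
    gamma,      # (n_sets, K)
    alpha,
    nu_g,
    s_g,
    nu_e,
    s_e,
    n_iter,
    burn_in,
    thin,
    seed,
    update_hyper,
    sigma2_g0,  # (n_sets,)
    sigma2_e0,
    pi0,        # (n_sets, K+1)
):
    np.random.seed(seed)
    n, p = X.shape
    K = gamma.shape[1]
    xtx = np.empty(p)
    for j in range(p):
        xtx[j] = np.dot(X[:, j], X[:, j])

    beta = np.zeros(p)
    comp = np.zeros(p, dtype=np.int8)
    resid = y.copy()
    sigma2_g = sigma2_g0.copy()
    sigma2_e = sigma2_e0
    pi = pi0.copy()

    n_keep = (n_iter - burn_in) // thin
    keep_beta = np.zeros((n_keep, p))
    keep_comp = np.zeros((n_keep, p), dtype=np.int8)
    keep_sg = np.zeros((n_keep, n_sets))
    keep_se = np.zeros(n_keep)
    keep_pi = np.zeros((n_keep, n_sets, K + 1))
    kept = 0
    status = 0

    lw = np.empty(K + 1)
    mus = np.empty(K)
    lams = np.empty(K)

    for it in range(n_iter):
        perm = np.random.permutation(p)
        for jj in range(p):
            j = perm[jj]
            s = set_id[j]
            rhs = (np.dot(X[:, j], resid) + xtx[j] * beta[j]) / sigma2_e
            lw[0] = np.log(pi[s, 0])
            for k in range(K):
                v = gamma[s, k] * sigma2_g[s]
                lam = xtx[j] / sigma2_e + 1.0 / v
                mu = rhs / lam
                lams[k] = lam
                mus[k] = mu
                lw[k + 1] = np.log(pi[s, k + 1]) - 0.5 * np.log(v * lam) + 0.5 * mu * mu * lam
            m = lw[0]
            for k in range(1, K + 1):
                if lw[k] > m:
                    m = lw[k]
            tot = 0.0
            for k in range(K + 1):
                lw[k] = np.exp(lw[k] - m)
                tot += lw[k]
            u = np.random.random() * tot
            c = K  # falls through to the last component
            acc = 0.0
            for k in range(K + 1):
                acc += lw[k]
                if u <= acc:
                    c = k
                    break
            old = beta[j]
            comp[j] = c
            if c == 0:
                beta[j] = 0.0
            else:
                beta[j] = np.random.normal(mus[c - 1], np.sqrt(1.0 / lams[c - 1]))
            if beta[j] != old:
                diff = old - beta[j]
                for i in range(n):
                    resid[i] += X[i, j] * diff

        if update_hyper:
            for s in range(n_sets):
                ssq = 0.0
                mcount = 0
                for j in range(p):
                    if set_id[j] == s and comp[j] > 0:
                        ssq += beta[j] * beta[j] / gamma[s, comp[j] - 1]
                        mcount += 1
                sigma2_g[s] = (ssq + nu_g * s_g) / np.random.chisquare(nu_g + mcount)
            rss = 0.0
            for i in range(n):
                rss += resid[i] * resid[i]
            sigma2_e = (rss + nu_e * s_e) / np.random.chisquare(nu_e + n)
            if not np.isfinite(sigma2_e) or sigma2_e < 1e-12:
                status = it + 1
                break
            for s in range(n_sets):
                tot = 0.0
                for k in range(K + 1):
                    cnt = 0
                    for j in range(p):
                        if set_id[j] == s and comp[j] == k:
                            cnt += 1
                    pi[s, k] = np.random.gamma(alpha + cnt, 1.0)
                    tot += pi[s, k]
                for k in range(K + 1):
                    pi[s, k] /= tot

        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            keep_beta[kept] = beta
            keep_comp[kept] = comp
            keep_sg[kept] = sigma2_g
            keep_se[kept] = sigma2_e
            keep_pi[kept] = pi
            kept += 1

    return keep_beta, keep_comp, keep_sg, keep_se, keep_pi, kept, status


def _as_matrix(marker_sets):
    """Stack one or two standardized MarkerMatrix objects column-wise."""
    if isinstance(marker_sets, MarkerMatrix):
        marker_sets = [marker_sets]
    labels, blocks, ids, set_index = [], [], [], []
    for s, mm in enumerate(marker_sets):
        if not mm.standardized:
            raise ValueError("markers must be standardized before sampling")
        x = mm.values.to_numpy(float)
        if np.isnan(x).any():
            raise ValueError("markers contain missing values; impute or filter first")
        set_label = mm.manifest["set"].iloc[0]
        labels.append(set_label)
        blocks.append(x)
        ids.extend(mm.values.columns)
        set_index.extend([s] * x.shape[1])
    # column-major so per-marker slices are contiguous in the sweep kernel
    return np.asfortranarray(np.hstack(blocks)), labels, ids, np.asarray(set_index, dtype=np.int64)


def run_gibbs(
    y,
    marker_sets,
    spec: MixtureSpec | None = None,
    config: GibbsConfig | None = None,
    fix_hyperparameters: dict | None = None,
) -> PosteriorDraws:
    """Run the Gibbs sampler over one or two marker sets.

    ``y`` is the standardized, covariate-residualized phenotype.  With
    ``fix_hyperparameters={'sigma2_g': [...], 'sigma2_e': x, 'pi': [[...]]}``
    the variance and proportion updates are disabled (oracle-comparison
    mode); the slab variances are then gamma_k * sigma2_g with the fixed
    scale.
    """
    spec = spec or MixtureSpec()
    config = config or GibbsConfig()
    X, labels, ids, set_index = _as_matrix(marker_sets)
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != X.shape[0]:
        raise ValueError("phenotype length does not match sample count")
    if abs(y.mean()) > 1e-6 or abs(y.var() - 1.0) > 1e-4:
        raise ValueError("phenotype must be standardized (mean 0, variance 1)")
    n_sets = len(labels)
    gamma = np.array([spec.gamma[l] for l in labels], dtype=float)

    if fix_hyperparameters is None:
        update = True
        sg0 = np.full(n_sets, y.var())
        se0 = y.var()
        pi0 = np.full((n_sets, _K + 1), spec.alpha)
        pi0 /= pi0.sum(axis=1, keepdims=True)
    else:
        update = False
        sg0 = np.asarray(fix_hyperparameters["sigma2_g"], dtype=float).ravel()
        se0 = float(fix_hyperparameters["sigma2_e"])
        pi0 = np.asarray(fix_hyperparameters["pi"], dtype=float)
        if pi0.ndim == 1:
            pi0 = pi0[None, :]

    betas, comps, sgs, ses, pis, chains = [], [], [], [], [], []
    for c in range(config.n_chains):
        seed = int((config.seed * 10_007 + c) % (2**31 - 1))
        kb, kc, ksg, kse, kpi, kept, status = _chain(
            X,
            set_index,
            n_sets,
            y,
            gamma,
            spec.alpha,
            spec.nu_g,
            spec.s_g,
            spec.nu_e,
            spec.s_e,
            config.n_iter,
            config.burn_in,
            config.thin,
            seed,
            update,
            sg0,
            se0,
            pi0,
        )
        if status != 0:
            raise RuntimeError(
                f"sampler diverged (residual variance underflow) in chain {c} at sweep {status}"
            )
        sl = slice(kept - config.retain_last, kept)
        betas.append(kb[sl])
        comps.append(kc[sl])
        sgs.append(ksg[sl])
        ses.append(kse[sl])
        pis.append(kpi[sl])
        chains.append(np.full(config.retain_last, c))

    return PosteriorDraws(
        beta=np.vstack(betas),
        components=np.vstack(comps),
        sigma2_g=np.vstack(sgs),
        sigma2_e=np.concatenate(ses),
        pi=np.vstack(pis),
        chain=np.concatenate(chains),
        marker_ids=list(ids),
        set_labels=labels,
        set_index=set_index,
        standardized_input=True,
        meta={"config": config, "spec": spec, "fixed": fix_hyperparameters is not None},
    )


def enumerate_posterior_oracle(y, X, gamma, sigma2_g, sigma2_e, pi):
    """Exact posterior by exhaustive enumeration over indicator configs.

    For p <= 8 markers and fixed hyperparameters, enumerates all (K+1)^p
    assignments of markers to {spike, components 1..K}, computes the
    closed-form Gaussian marginal likelihood with effects integrated out
    (covariance sigma2_e I + X_c V_c X_c^T via the Woodbury identity),
    and returns ``(pips, config_posterior)`` where ``config_posterior``
    maps each configuration tuple to its exact posterior probability.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p > 8:
        raise ValueError("enumeration oracle is limited to p <= 8 markers")
    gamma = np.asarray(gamma, dtype=float).ravel()
    pi = np.asarray(pi, dtype=float).ravel()
    K = gamma.size
    if pi.size != K + 1:
        raise ValueError("pi must have one spike plus K component weights")
    v = gamma * float(sigma2_g)  # absolute slab variances
    base_quad = y @ y / sigma2_e
    log_pi = np.log(pi)

    log_posts = []
    configs = list(itertools.product(range(K + 1), repeat=p))
    for cfg in configs:
        nz = [j for j in range(p) if cfg[j] > 0]
        lp = sum(log_pi[c] for c in cfg)
        if not nz:
            ll = -0.5 * (n * np.log(sigma2_e) + base_quad)
        else:
            Xc = X[:, nz]
            vc = np.array([v[cfg[j] - 1] for j in nz])
            M = Xc.T @ Xc / sigma2_e + np.diag(1.0 / vc)
            sign, logdet_m = np.linalg.slogdet(M)
            b = Xc.T @ y / sigma2_e
            quad = base_quad - b @ np.linalg.solve(M, b)
            logdet = n * np.log(sigma2_e) + np.log(vc).sum() + logdet_m
            ll = -0.5 * (logdet + quad)
        log_posts.append(lp + ll)
    log_posts = np.asarray(log_posts)
    w = np.exp(log_posts - log_posts.max())
    w /= w.sum()

    pips = np.zeros(p)
    for cfg, prob in zip(configs, w):
        for j in range(p):
            if cfg[j] > 0:
                pips[j] += prob
    return pips, dict(zip(configs, w))


def _split_chains(x: np.ndarray) -> np.ndarray:
    """Split each chain's draws in half: (chains, draws) -> (2*chains, draws//2)."""
    nc, nd = x.shape
    half = nd // 2
    return np.vstack([x[:, :half], x[:, nd - half:]])


def _rhat(x: np.ndarray) -> float:
    x = _split_chains(x)
    m, nd = x.shape
    if nd < 2:
        return np.nan
    means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = nd * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_hat = (nd - 1) / nd * w + b / nd
    return float(np.sqrt(var_hat / w))


def _ess(x: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    m, nd = x.shape
    total = m * nd
    xc = x - x.mean(axis=1, keepdims=True)
    if np.allclose(xc, 0):
        return float(total)
    acov = np.zeros(nd)
    for t in range(nd):
        acov[t] = np.mean([np.dot(xc[c, : nd - t], xc[c, t:]) / nd for c in range(m)])
    rho = acov / acov[0]
    tau = 1.0
    t = 1
    while t + 1 < nd:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2 * pair
        t += 2
    return float(total / tau)


def convergence_diagnostics(draws: PosteriorDraws, rhat_max: float = 1.1):
    """Split-R-hat and effective sample size for the key scalar traces.

    Monitors residual variance, per-set effect-variance scales and the
    per-set variance explained.  Requires at least two chains; returns a
    dict of ``{quantity: {'rhat': r, 'ess': e, 'flag': bool}}``.
    """
    chains = np.unique(draws.chain)
    if chains.size < 2:
        raise ValueError("convergence diagnostics need at least two chains")

    def per_chain(vec):
        return np.vstack([vec[draws.chain == c] for c in chains])

    quantities = {"sigma2_e": per_chain(draws.sigma2_e)}
    for s, label in enumerate(draws.set_labels):
        quantities[f"sigma2_g[{label}]"] = per_chain(draws.sigma2_g[:, s])
        cols = np.flatnonzero(draws.set_index == s)
        ve = (draws.beta[:, cols] ** 2).sum(axis=1)
        quantities[f"var_explained[{label}]"] = per_chain(ve)

    out = {}
    for name, mat in quantities.items():
        r = _rhat(mat)
        out[name] = {"rhat": r, "ess": _ess(mat), "flag": bool(r > rhat_max)}
    return out
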