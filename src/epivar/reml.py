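"""Variance-component estimation from an omics relationship matrix.

The sensitivity analysis mirrors the mixed-linear-model route to the
variance explained by all markers: compute an omics relationship matrix
(ORM) A = Z Z^T / p from the standardized sample x marker matrix Z —
analogous to a genomic relationship matrix — then fit

    y ~ N(X tau, sigma2_A A + sigma2_e I)

by average-information REML (with a damped gradient fallback step when
the AI update misbehaves), initialized from the Haseman-Elston moment
estimator, and report m2 = sigma2_A / (sigma2_A + sigma2_e) with its
approximate standard error.  X is an intercept column.  The fit works in
the eigenbasis of A, so after one symmetric eigendecomposition every
REML iteration costs O(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MarkerMatrix


@dataclass
class OmicsRelationshipMatrix:
    matrix: np.ndarray
    n_markers: int
    set_label: str
    sample_ids: list

    def __post_init__(self) -> None:
        a = self.matrix
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("ORM must be square")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("ORM must be symmetric")


@dataclass
class RemlResult:
    m2: float
    se: float
    sigma2_a: float
    sigma2_e: float
    loglik: float
    n_iter: int
    converged: bool
    boundary: bool
    trace: list


def compute_orm(markers: MarkerMatrix) -> OmicsRelationshipMatrix:
    """A = Z Z^T / p over the standardized, complete marker matrix."""
    if not markers.standardized:
        raise ValueError("markers must be standardized before computing an ORM")
    z = markers.values.to_numpy(float)
    if np.isnan(z).any():
        raise ValueError("missing marker values; impute before computing the ORM")
    a = z @ z.T / z.shape[1]
    return OmicsRelationshipMatrix(
        matrix=a,
        n_markers=z.shape[1],
        set_label=str(markers.manifest["set"].iloc[0]),
        sample_ids=list(markers.values.index),
    )


def haseman_elston(y, orm: OmicsRelationshipMatrix) -> float:
    """Moment estimate of sigma2_A: regress y_i y_j on A_ij (i < j).

    Under the model E[y_i y_j] = sigma2_A A_ij for i != j (y centred),
    the off-diagonal regression slope estimates sigma2_A.
    """
    y = np.asarray(y, dtype=float).ravel()
    y = y - y.mean()
    a = orm.matrix
    iu = np.triu_indices_from(a, k=1)
    x = a[iu]
    if np.ptp(x) == 0:
        raise ValueError("no off-diagonal variation in the ORM (A proportional to I)")
    cp = np.outer(y, y)[iu]
    x_c = x - x.mean()
    return float(x_c @ (cp - cp.mean()) / (x_c @ x_c))


class _RotatedReml:
    """REML quantities in the eigenbasis of A (intercept-only fixed effects)."""

    def __init__(self, y: np.ndarray, a: np.ndarray):
        n = y.size
        w, u = np.linalg.eigh(a)
        self.w = np.maximum(w, 0.0)  # clip tiny negative eigenvalues
        self.ys = u.T @ y
        self.xs = u.T @ np.ones(n)
        self.n = n

    def parts(self, s2a: float, s2e: float):
        d = s2a * self.w + s2e
        if np.any(d <= 0):
            return None
        xvx = np.sum(self.xs**2 / d)
        xvy = np.sum(self.xs * self.ys / d)
        # py = P y in the rotated basis
        py = self.ys / d - (self.xs / d) * (xvy / xvx)
        ll = -0.5 * (np.log(d).sum() + np.log(xvx) + self.ys @ py)
        return d, xvx, py, ll

    def trace_p_times(self, d: float, xvx: float, weights: np.ndarray) -> float:
        """tr(P diag(weights)) where P is in the rotated basis."""
        return float(np.sum(weights / d) - np.sum(self.xs**2 * weights / d**2) / xvx)

    def apply_p(self, d: np.ndarray, xvx: float, v: np.ndarray) -> np.ndarray:
        return v / d - (self.xs / d) * np.sum(self.xs * v / d) / xvx


def reml_fit(
    y,
    orm: OmicsRelationshipMatrix,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> RemlResult:
    """AI-REML for the one-component model y ~ N(mu, s2a A + s2e I).

    Initialized from Haseman-Elston; iterates average-information updates
    of (s2a, s2e), falling back to a damped gradient step (EM-flavoured,
    guaranteed uphill) when the AI system is singular or the AI step
    lowers the restricted likelihood.  Convergence is declared when the
    log-likelihood changes by less than ``tol``; stalling with no ascent
    direction is also treated as an optimum.  The variance share is
    clamped to [0, 1] and flagged when it sits on the boundary.
    """
    y = np.asarray(y, dtype=float).ravel()
    a = orm.matrix
    n = y.size
    if a.shape[0] != n:
        raise ValueError("phenotype length does not match the ORM")

    vary = y.var(ddof=1)
    s2a = min(max(haseman_elston(y, orm), 0.01 * vary), 0.99 * vary)
    s2e = max(vary - s2a, 0.01 * vary)
    rot = _RotatedReml(y, a)

    parts = rot.parts(s2a, s2e)
    if parts is None:
        raise RuntimeError("initial variance matrix not positive definite")
    d, xvx, py, ll = parts
    trace = [(0, s2a, s2e, ll)]
    converged = False
    ai = None
    floor = 1e-8 * vary

    for it in range(1, max_iter + 1):
        apy = rot.w * py  # A P y in the rotated basis
        grad = np.array(
            [
                -0.5 * (rot.trace_p_times(d, xvx, rot.w) - py @ apy),
                -0.5 * (rot.trace_p_times(d, xvx, np.ones(n)) - py @ py),
            ]
        )
        pay = rot.apply_p(d, xvx, apy)
        ppy = rot.apply_p(d, xvx, py)
        ai = 0.5 * np.array(
            [[apy @ pay, apy @ ppy], [apy @ ppy, py @ ppy]]
        )
        # active set: parameters pinned at the floor with a downhill
        # gradient stay fixed (boundary of the parameter space)
        theta = np.array([s2a, s2e])
        active = ~((theta <= floor * (1 + 1e-12)) & (grad < 0))
        if not active.any():
            converged = True
            break
        accepted = False
        step = np.zeros(2)
        try:
            idx = np.flatnonzero(active)
            step[idx] = np.linalg.solve(ai[np.ix_(idx, idx)], grad[idx])
        except np.linalg.LinAlgError:
            step = None
        if step is not None and np.all(np.isfinite(step)):
            frac = 1.0
            for _ in range(10):  # backtrack the AI step if it goes downhill
                cand = np.maximum(theta + frac * step, floor)
                new = rot.parts(*cand)
                if new is not None and new[3] >= ll - 1e-10:
                    s2a, s2e = cand
                    d, xvx, py, ll = new
                    accepted = True
                    break
                frac *= 0.5
        if not accepted:
            # damped gradient fallback with step halving, restricted to
            # the active parameters
            scale = np.where(active, theta**2 * (2.0 / n), 0.0)
            ok = False
            for _ in range(30):
                cand = np.maximum(theta + scale * grad, floor)
                new = rot.parts(*cand)
                if new is not None and new[3] >= ll - 1e-12:
                    ok = True
                    break
                scale *= 0.5
            if not ok or np.allclose(cand, theta, rtol=1e-12, atol=0):
                converged = True  # no ascent available: optimum (or boundary)
                break
            s2a, s2e = cand
            d, xvx, py, ll = new
        trace.append((it, s2a, s2e, ll))
        if abs(trace[-1][3] - trace[-2][3]) < tol:
            converged = True
            break

    if not converged:
        raise RuntimeError(
            f"REML did not converge in {max_iter} iterations; last steps: {trace[-5:]}"
        )

    total = s2a + s2e
    m2 = s2a / total
    try:
        cov = np.linalg.inv(ai)
        deriv = np.array([s2e, -s2a]) / total**2
        se = float(np.sqrt(max(deriv @ cov @ deriv, 0.0)))
    except (np.linalg.LinAlgError, TypeError):
        se = float("nan")
    boundary = bool(m2 < 1e-6 or m2 > 1 - 1e-6)
    m2 = float(np.clip(m2, 0.0, 1.0))
    return RemlResult(
        m2=m2,
        se=se,
        sigma2_a=float(s2a),
        sigma2_e=float(s2e),
        loglik=float(ll),
        n_iter=len(trace) - 1,
        converged=converged,
        boundary=boundary,
        trace=trace,
    )
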