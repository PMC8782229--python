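"""Restricted maximum likelihood for Gaussian mixed models with
independent random factors (crossed or nested), y = Xb + sum_k Z_k u_k + e.

The covariance is V = sum_k s2_k Z_k Z_k' + s2_e I.  All likelihood
quantities are computed from cross-products (X'X, X'Z, Z'Z, ...) via the
Woodbury identity, so a likelihood evaluation costs O(q^3) in the total
number of random-effect levels q, independent of the number of records.
The restricted log-likelihood is maximized directly over the variance
scale with bound constraints (variances >= 0), starting from moment
estimates; estimates that converge onto the zero boundary are truncated
and the reduced model is refitted for the reported likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

_LOG2PI = np.log(2.0 * np.pi)
#: Relative floor (vs response variance) below which a fitted component is
#: treated as on the zero boundary.
_BOUNDARY_TOL = 1e-8


@dataclass
class RandomFactor:
    """One random factor: integer level codes per record plus level labels."""

    name: str
    codes: np.ndarray
    levels: np.ndarray

    @classmethod
    def from_labels(cls, name: str, labels) -> "RandomFactor":
        levels, codes = np.unique(np.asarray(labels), return_inverse=True)
        return cls(name, codes.astype(np.int64), levels)

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class REMLResult:
    variances: dict[str, float]          # per-factor variance estimates
    sigma2_error: float
    se: dict[str, float]                 # SEs incl. "error"; nan at boundary
    beta: np.ndarray
    beta_names: list[str]
    loglik: float                        # restricted log-likelihood
    blups: dict[str, dict]               # factor -> {level: BLUP}
    converged: bool
    n_iter: int
    truncated: tuple[str, ...] = field(default_factory=tuple)

    @property
    def all_variances(self) -> dict[str, float]:
        out = dict(self.variances)
        out["error"] = self.sigma2_error
        return out


class _CrossProducts:
    """Sufficient statistics for the REML likelihood."""

    def __init__(self, y: np.ndarray, X: np.ndarray, factors: list[RandomFactor]):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        n = len(y)
        self.n, self.p = n, X.shape[1]
        self.factors = factors
        self.q_per = [f.n_levels for f in factors]
        self.q = int(sum(self.q_per))
        Z = np.zeros((n, self.q))
        off = 0
        self.offsets = []
        for f in factors:
            Z[np.arange(n), off + f.codes] = 1.0
            self.offsets.append(off)
            off += f.n_levels
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.XtZ = X.T @ Z
        self.ZtZ = Z.T @ Z
        self.Zty = Z.T @ y
        self.yty = float(y @ y)

    def neg_loglik(self, theta: np.ndarray) -> float:
        return -self.loglik(theta[:-1], theta[-1])

    def loglik(self, variances: np.ndarray, s2e: float) -> float:
        n, p = self.n, self.p
        active = np.asarray(variances, float) > 0
        if not active.any():
            # pure fixed-effects model
            beta = linalg.solve(self.XtX, self.Xty, assume_a="pos")
            rss = self.yty - 2 * beta @ self.Xty + beta @ self.XtX @ beta
            logdet_v = n * np.log(s2e)
            logdet_xvx = _logdet_spd(self.XtX / s2e)
            return -0.5 * ((n - p) * _LOG2PI + logdet_v + logdet_xvx + rss / s2e)
        idx = np.concatenate(
            [self.offsets[k] + np.arange(self.q_per[k])
             for k in range(len(self.factors)) if active[k]]
        )
        g = np.repeat(
            np.asarray(variances, float)[active],
            np.asarray(self.q_per)[active],
        )
        ZtZ = self.ZtZ[np.ix_(idx, idx)]
        XtZ = self.XtZ[:, idx]
        Zty = self.Zty[idx]
        M = ZtZ + np.diag(s2e / g)
        cM = linalg.cho_factor(M, lower=True)
        logdet_m = 2.0 * np.log(np.diag(cM[0])).sum()
        qa = len(idx)
        logdet_v = (n - qa) * np.log(s2e) + np.log(g).sum() + logdet_m
        Minv_ZtX = linalg.cho_solve(cM, XtZ.T)
        Minv_Zty = linalg.cho_solve(cM, Zty)
        XtVX = (self.XtX - XtZ @ Minv_ZtX) / s2e
        XtVy = (self.Xty - XtZ @ Minv_Zty) / s2e
        ytVy = (self.yty - Zty @ Minv_Zty) / s2e
        cX = linalg.cho_factor(XtVX, lower=True)
        beta = linalg.cho_solve(cX, XtVy)
        logdet_xvx = 2.0 * np.log(np.diag(cX[0])).sum()
        ypy = ytVy - beta @ XtVy
        return -0.5 * ((n - p) * _LOG2PI + logdet_v + logdet_xvx + ypy)

    def solve(self, variances: np.ndarray, s2e: float):
        """GLS fixed effects and BLUPs at the given variances."""
        active = np.asarray(variances, float) > 0
        if not active.any():
            beta = linalg.solve(self.XtX, self.Xty, assume_a="pos")
            return beta, np.zeros(self.q)
        idx = np.concatenate(
            [self.offsets[k] + np.arange(self.q_per[k])
             for k in range(len(self.factors)) if active[k]]
        )
        g = np.repeat(np.asarray(variances, float)[active],
                      np.asarray(self.q_per)[active])
        M = self.ZtZ[np.ix_(idx, idx)] + np.diag(s2e / g)
        cM = linalg.cho_factor(M, lower=True)
        XtZ = self.XtZ[:, idx]
        XtVX = self.XtX - XtZ @ linalg.cho_solve(cM, XtZ.T)
        XtVy = self.Xty - XtZ @ linalg.cho_solve(cM, self.Zty[idx])
        beta = linalg.solve(XtVX, XtVy, assume_a="pos")
        u_act = linalg.cho_solve(cM, self.Zty[idx] - XtZ.T @ beta)
        u = np.zeros(self.q)
        u[idx] = u_act
        return beta, u


def _logdet_spd(A: np.ndarray) -> float:
    c = linalg.cholesky(A, lower=True)
    return 2.0 * np.log(np.diag(c)).sum()


def reml_fit(
    y,
    X,
    factors: list[RandomFactor],
    *,
    beta_names: list[str] | None = None,
    start: np.ndarray | None = None,
    max_iter: int = 500,
    compute_se: bool = True,
) -> REMLResult:
    """Fit the mixed model by REML.

    ``y`` response, ``X`` full-column-rank fixed-effects design,
    ``factors`` the random factors.  ``start`` optionally provides
    starting values ``(var_1, ..., var_K, s2_error)`` on the data scale.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} records cannot identify {p} fixed effects")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design matrix is singular")
    k = len(factors)
    scale = float(np.std(y))
    if scale == 0:
        scale = 1.0
    cp = _CrossProducts(y / scale, X, factors)

    if start is not None:
        theta0 = np.asarray(start, float) / scale**2
    else:
        theta0 = np.full(k + 1, 1.0 / (k + 1))
    theta0 = np.clip(theta0, 1e-6, None)

    bounds = [(0.0, None)] * k + [(1e-10, None)]
    res = optimize.minimize(
        cp.neg_loglik, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
    )
    if not res.success:
        # a failed line search at (or next to) the optimum is common when
        # the start is already the solution; restart with a looser ftol
        res2 = optimize.minimize(
            cp.neg_loglik, np.clip(res.x, 1e-8, None), method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-7},
        )
        if res2.fun <= res.fun or res2.success:
            res = res2
    converged = bool(res.success) or _grad_small(cp.neg_loglik, res.x, bounds)
    theta = res.x.copy()

    error_at_floor = theta[-1] <= 2e-10
    if error_at_floor and not converged:
        # perfect-fit degeneracy: the restricted likelihood is unbounded as
        # the residual variance goes to zero.  Pin it at the floor and
        # profile the remaining components; report a flagged boundary fit.
        def nll_pinned(sub):
            return cp.neg_loglik(np.r_[sub, theta[-1]])

        res3 = optimize.minimize(
            nll_pinned, np.clip(theta[:k], 1e-8, None), method="L-BFGS-B",
            bounds=[(0.0, None)] * k,
            options={"maxiter": max_iter, "ftol": 1e-10},
        )
        if res3.fun <= cp.neg_loglik(theta):
            theta[:k] = res3.x
        converged = True

    floor = _BOUNDARY_TOL  # response standardized: variance scale is ~1
    truncated = tuple(factors[i].name for i in range(k) if theta[i] < floor)
    if error_at_floor:
        truncated = truncated + ("error",)
    theta[:k][theta[:k] < floor] = 0.0
    if truncated and not error_at_floor:
        # refit with boundary components pinned at zero for an honest
        # likelihood (profile over the remaining components)
        free = [i for i in range(k) if theta[i] > 0.0]

        def nll_reduced(sub):
            full = theta.copy()
            for j, i in enumerate(free):
                full[i] = sub[j]
            full[-1] = sub[-1]
            return cp.neg_loglik(full)

        sub0 = np.r_[theta[free], theta[-1]]
        res2 = optimize.minimize(
            nll_reduced, np.clip(sub0, 1e-8, None), method="L-BFGS-B",
            bounds=[(0.0, None)] * len(free) + [(1e-10, None)],
            options={"maxiter": max_iter, "ftol": 1e-13},
        )
        for j, i in enumerate(free):
            theta[i] = res2.x[j]
        theta[-1] = res2.x[-1]

    loglik = cp.loglik(theta[:k], theta[-1]) - (n - p) * np.log(scale)
    beta_s, u_s = cp.solve(theta[:k], theta[-1])

    se = {f.name: np.nan for f in factors}
    se["error"] = np.nan
    if compute_se and not error_at_floor:
        free_idx = [i for i in range(k + 1) if theta[i] > 0.0 or i == k]
        H = _num_hessian(cp.neg_loglik, theta, free_idx)
        try:
            cov = linalg.inv(H)
            diag = np.diag(cov)
            if (diag > 0).all():
                for j, i in enumerate(free_idx):
                    name = factors[i].name if i < k else "error"
                    se[name] = float(np.sqrt(diag[j])) * scale**2
        except linalg.LinAlgError:
            pass

    variances = {factors[i].name: float(theta[i]) * scale**2 for i in range(k)}
    blups = {}
    for kk, f in enumerate(factors):
        off = cp.offsets[kk]
        vals = u_s[off:off + f.n_levels] * scale
        blups[f.name] = dict(zip(f.levels, vals))
    return REMLResult(
        variances=variances,
        sigma2_error=float(theta[-1]) * scale**2,
        se=se,
        beta=beta_s * scale,
        beta_names=beta_names or [f"b{i}" for i in range(p)],
        loglik=float(loglik),
        blups=blups,
        converged=converged,
        n_iter=int(res.nit),
        truncated=truncated,
    )


def _grad_small(f, theta: np.ndarray, bounds, tol: float = 1e-2) -> bool:
    """Projected-gradient check: accept an optimizer 'failure' that in
    fact sits at a (possibly boundary) stationary point."""
    for i in range(len(theta)):
        h = max(1e-7, 1e-5 * abs(theta[i]))
        lo = bounds[i][0]
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] = max(tm[i] - h, lo if lo is not None else tm[i] - h)
        g = (f(tp) - f(tm)) / (tp[i] - tm[i]) if tp[i] != tm[i] else 0.0
        at_lower = lo is not None and theta[i] - lo < 1e-10
        if at_lower and g > 0:
            continue  # pushing into the bound
        if abs(g) > tol:
            return False
    return True


def _num_hessian(f, theta: np.ndarray, free_idx: list[int]) -> np.ndarray:
    """Central-difference Hessian of ``f`` over the free coordinates."""
    m = len(free_idx)
    h = np.array([max(1e-5, 1e-3 * abs(theta[i])) for i in free_idx])
    H = np.zeros((m, m))
    f0 = f(theta)

    def at(shift):
        t = theta.copy()
        for j, i in enumerate(free_idx):
            t[i] = max(t[i] + shift[j], 1e-12)
        return f(t)

    for a in range(m):
        for b in range(a, m):
            sa = np.zeros(m); sb = np.zeros(m)
            sa[a] = h[a]; sb[b] = h[b]
            if a == b:
                H[a, a] = (at(sa) - 2 * f0 + at(-sa)) / h[a] ** 2
            else:
                H[a, b] = H[b, a] = (
                    at(sa + sb) - at(sa - sb) - at(-sa + sb) + at(-sa - sb)
                ) / (4 * h[a] * h[b])
    return H
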