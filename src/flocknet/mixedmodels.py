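"""Random-intercept mixed models used by the inference stage.

Two fitters for the single-grouping-factor designs the analysis needs:

* :func:`fit_lmm` — Gaussian linear mixed model with one random intercept,
  fitted by (restricted) maximum likelihood.  The variance-ratio profile
  reduces the problem to a one-dimensional optimisation with closed-form
  GLS inside, which makes permutation re-fits cheap.  Estimates agree with
  ``statsmodels`` MixedLM (cross-checked in the test suite).
* :func:`fit_poisson_glmm` — Poisson GLMM with log link and one random
  intercept, fitted by maximum likelihood with the cluster likelihood
  integrated by Gauss–Hermite quadrature.

Both return a :class:`MixedFit` with coefficients, standard errors and
variance components.  Inference downstream relies on permutation p-values,
so asymptotic standard errors are reported for scale only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["MixedFit", "fit_lmm", "fit_poisson_glmm"]


@dataclass
class MixedFit:
    """Result of a random-intercept model fit."""

    params: np.ndarray            # fixed-effect estimates
    se: np.ndarray                # asymptotic standard errors
    names: list[str]
    sigma_u: float                # random-intercept SD
    sigma_e: float | None         # residual SD (Gaussian only)
    loglike: float
    family: str
    converged: bool = True
    singular: bool = False        # sigma_u estimated at the zero boundary
    extra: dict = field(default_factory=dict)

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.se

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])


def _group_index(ids) -> tuple[np.ndarray, int]:
    _, inv = np.unique(np.asarray(ids), return_inverse=True)
    return inv, int(inv.max()) + 1


def fit_lmm(
    y,
    X,
    ids,
    names: list[str] | None = None,
    reml: bool = True,
) -> MixedFit:
    """Gaussian LMM  y = Xβ + u_group + ε  with u ~ N(0, σ_u²).

    The marginal covariance is σ_e²(I + λ Z Zᵀ) with λ = σ_u²/σ_e².  For a
    single grouping factor V⁻¹ is block diagonal with the Sherman–Morrison
    form I − λ/(1 + λ n_g) J per cluster, so the profiled (RE)ML criterion
    in log λ is evaluated in O(N p²) and optimised on a 1-D grid + Brent.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    g, n_groups = _group_index(ids)

    order = np.argsort(g, kind="stable")
    y_s, X_s, g_s = y[order], X[order], g[order]
    counts = np.bincount(g_s, minlength=n_groups)
    starts = np.concatenate([[0], np.cumsum(counts)])

    # cluster-wise sums reused across lambda evaluations
    sum_X = np.add.reduceat(X_s, starts[:-1], axis=0)      # (G, p)
    sum_y = np.add.reduceat(y_s, starts[:-1])              # (G,)
    XtX = X_s.T @ X_s
    Xty = X_s.T @ y_s
    yty = float(y_s @ y_s)

    def gls(lam: float):
        """GLS fit at variance ratio lam; returns criterion pieces."""
        shrink = lam / (1.0 + lam * counts)                # (G,)
        A = XtX - (sum_X * shrink[:, None]).T @ sum_X
        b = Xty - sum_X.T @ (shrink * sum_y)
        beta = np.linalg.solve(A, b)
        # residual quadratic form r' V^{-1} r
        quad = (
            yty
            - float(shrink @ (sum_y**2))
            - 2 * float(beta @ b)
            + float(beta @ (A @ beta))
        )
        logdet_v = float(np.sum(np.log1p(lam * counts)))
        return beta, A, quad, logdet_v

    dof = n - p if reml else n

    def crit(loglam: float) -> float:
        lam = np.exp(loglam)
        beta, A, quad, logdet_v = gls(lam)
        quad = max(quad, 1e-300)
        c = logdet_v + dof * np.log(quad / dof)
        if reml:
            sign, logdet_a = np.linalg.slogdet(A)
            c += logdet_a
        return c

    # coarse grid then local refinement; include the boundary lam ~ 0
    grid = np.linspace(-12.0, 8.0, 41)
    vals = [crit(v) for v in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(crit, bounds=(lo, hi), method="bounded")
    loglam = float(res.x) if res.fun <= vals[k] else grid[k]
    lam = float(np.exp(loglam))

    beta, A, quad, logdet_v = gls(lam)
    sigma2_e = quad / dof
    singular = lam < 1e-5
    if singular:
        lam = 0.0
        beta, A, quad, logdet_v = gls(0.0)
        sigma2_e = quad / dof
    sigma2_u = lam * sigma2_e
    cov = np.linalg.inv(A) * sigma2_e
    se = np.sqrt(np.diag(cov))

    ll = -0.5 * (logdet_v + n * np.log(2 * np.pi * sigma2_e) + quad / sigma2_e)
    return MixedFit(
        params=beta,
        se=se,
        names=list(names),
        sigma_u=float(np.sqrt(sigma2_u)),
        sigma_e=float(np.sqrt(sigma2_e)),
        loglike=float(ll),
        family="gaussian",
        singular=singular,
        extra={"lambda": lam, "reml": reml},
    )


def fit_poisson_glmm(
    y,
    X,
    ids,
    names: list[str] | None = None,
    n_quad: int = 25,
) -> MixedFit:
    """Poisson GLMM  y ~ Poisson(exp(Xβ + u_group)),  u ~ N(0, σ_u²).

    The per-cluster likelihood is integrated over the random intercept by
    Gauss–Hermite quadrature (``n_quad`` nodes) and the marginal
    log-likelihood maximised over (β, log σ_u) with BFGS.  Standard errors
    come from the inverse numerical Hessian at the optimum.
    """
    y = np.asarray(y, float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("Poisson family requires non-negative integer counts")
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    g, n_groups = _group_index(ids)

    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    logw = np.log(weights / np.sqrt(2 * np.pi))  # probabilists' weights

    def negll(theta: np.ndarray) -> float:
        beta, logsig = theta[:p], theta[p]
        sig = np.exp(logsig)
        eta = X @ beta                                   # (n,)
        # per observation, per node: y*(eta+sig*a) - exp(eta+sig*a)
        shift = sig * nodes                              # (Q,)
        contrib = (
            y[:, None] * (eta[:, None] + shift[None, :])
            - np.exp(eta[:, None] + shift[None, :])
        )
        # sum within clusters -> (G, Q)
        cluster = np.zeros((n_groups, n_quad))
        np.add.at(cluster, g, contrib)
        m = cluster.max(axis=1, keepdims=True)
        log_int = m[:, 0] + np.log(
            np.exp(cluster - m + logw[None, :]).sum(axis=1)
        )
        return -float(log_int.sum())

    # start from the pooled Poisson GLM (IRLS-free: a few Newton steps)
    beta0 = np.zeros(p)
    beta0[0] = np.log(max(y.mean(), 1e-8))
    theta0 = np.concatenate([beta0, [np.log(0.5)]])
    res = optimize.minimize(negll, theta0, method="BFGS",
                            options={"gtol": 1e-7, "maxiter": 500})
    theta = res.x
    sigma_u = float(np.exp(theta[p]))

    # observed-information SEs for beta via central differences
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    k = p + 1
    hess = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            f = (
                negll(theta + ei + ej)
                - negll(theta + ei - ej)
                - negll(theta - ei + ej)
                + negll(theta - ei - ej)
            ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = f
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)

    # gradient can stall within tolerance of the optimum on flat
    # likelihoods; treat a finite solution with tiny gradient as converged
    converged = bool(res.success) or float(np.abs(res.jac).max()) < 1e-3
    return MixedFit(
        params=theta[:p],
        se=se,
        names=list(names),
        sigma_u=sigma_u,
        sigma_e=None,
        loglike=-float(res.fun),
        family="poisson",
        converged=converged,
        singular=sigma_u < 1e-4,
        extra={"n_quad": n_quad},
    )
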