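"""Logistic mixed model with a single random intercept.

The marginal likelihood integrates the random intercept out of each group's
Bernoulli likelihood with Gauss-Hermite quadrature (exact as the number of
nodes grows; the integrals are one-dimensional because the only random term
is the intercept). Maximum likelihood estimates come from BFGS with analytic
gradients; standard errors from the numerical Hessian of the marginal
log-likelihood at the optimum.

``k`` counts the intercept, the fixed effects and the random-intercept
variance, so AICc comparisons across fixed-effect structures are coherent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, log_expit
from statsmodels.tools.numdiff import approx_fprime

__all__ = ["GlmmFit", "fit_logistic_glmm"]


@dataclass
class GlmmFit:
    """Fitted random-intercept logistic model (marginal ML)."""

    terms: list[str]               # includes "(Intercept)"
    params: pd.Series              # fixed effects
    se: pd.Series
    re_sd: float                   # random-intercept SD
    loglik: float
    k: int                         # fixed effects + 1 variance component
    n: int
    n_groups: int
    converged: bool
    name: str = "glmm"

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.se

    @property
    def aicc(self) -> float:
        from .survival import aicc
        return aicc(self.loglik, self.k, self.n)


def _pack(beta: np.ndarray, log_sd: float) -> np.ndarray:
    return np.concatenate([beta, [log_sd]])


def fit_logistic_glmm(x: pd.DataFrame, y, groups, n_quad: int = 25,
                      add_intercept: bool = True, name: str = "glmm",
                      compute_se: bool = True) -> GlmmFit:
    """Fit ``y ~ x + (1 | groups)`` with y binary.

    ``x`` holds the fixed-effect columns (no intercept; one is added unless
    ``add_intercept=False``). Raises on complete separation symptoms
    (non-finite optimum) and degenerate inputs.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary")
    xmat = x.to_numpy(dtype=float)
    terms = list(x.columns)
    if add_intercept:
        xmat = np.column_stack([np.ones(len(y)), xmat])
        terms = ["(Intercept)"] + terms
    if len(y) != len(xmat):
        raise ValueError("length mismatch between response and design")
    if np.linalg.matrix_rank(xmat) < xmat.shape[1]:
        raise ValueError("design matrix is rank deficient")
    codes, _ = pd.factorize(np.asarray(groups))
    n_g = codes.max() + 1

    # standardize non-constant columns internally for optimizer stability
    col_mean = xmat.mean(axis=0) if add_intercept else np.zeros(xmat.shape[1])
    col_sd = xmat.std(axis=0)
    scale_mask = col_sd > 0
    col_mean[~scale_mask] = 0.0
    col_sd[~scale_mask] = 1.0
    xstd = (xmat - col_mean) / col_sd

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    u = np.sqrt(2.0) * nodes                  # N(0,1) abscissae
    logw = np.log(weights / np.sqrt(np.pi))   # N(0,1) quadrature log-weights
    sign = 2.0 * y - 1.0                      # Bernoulli loglik via log sigmoid

    def _parts(theta):
        beta, log_sd = theta[:-1], theta[-1]
        sd = np.exp(log_sd)
        eta = xstd @ beta                                  # (n,)
        z = sign[:, None] * (eta[:, None] + sd * u[None, :])
        ll_rows = log_expit(z)                             # (n, q)
        ll_g = np.zeros((n_g, n_quad))
        np.add.at(ll_g, codes, ll_rows)
        ll_g = ll_g + logw[None, :]
        m = ll_g.max(axis=1, keepdims=True)
        post = np.exp(ll_g - m)
        norm = post.sum(axis=1, keepdims=True)
        loglik = float((m[:, 0] + np.log(norm[:, 0])).sum())
        post /= norm                                       # (G, q) posterior node weights
        return loglik, post, eta, sd

    def nll(theta):
        return -_parts(theta)[0]

    def grad(theta):
        loglik, post, eta, sd = _parts(theta)
        mu = expit(eta[:, None] + sd * u[None, :])         # (n, q)
        r = y[:, None] - mu
        w_rows = post[codes]                               # (n, q)
        rw = r * w_rows
        g_beta = xstd.T @ rw.sum(axis=1)
        g_logsd = float((rw * (sd * u[None, :])).sum())
        return -np.concatenate([g_beta, [g_logsd]])

    # warm start from an ordinary logistic fit on the standardized design
    import statsmodels.api as sm
    with np.errstate(all="ignore"):
        try:
            beta0 = sm.GLM(y, xstd, family=sm.families.Binomial()).fit(
                maxiter=50).params
        except Exception:
            beta0 = np.zeros(xstd.shape[1])
    beta0 = np.nan_to_num(np.asarray(beta0), nan=0.0, posinf=0.0, neginf=0.0)
    theta0 = _pack(beta0, np.log(0.5))
    bounds = [(-30.0, 30.0)] * xstd.shape[1] + [(-6.0, 3.0)]
    with np.errstate(over="ignore", invalid="ignore"):
        res = optimize.minimize(nll, theta0, jac=grad, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-11})
    theta = res.x
    if not np.all(np.isfinite(theta)) or not np.isfinite(res.fun) \
            or np.any(np.abs(theta[:-1]) >= 29.9):
        raise FloatingPointError("GLMM optimum is not finite (possible "
                                 "complete separation)")
    loglik = -float(res.fun)

    # back-transform to the raw covariate scale
    p = xstd.shape[1]
    amat = np.zeros((p, p))
    for j in range(p):
        amat[j, j] = 1.0 / col_sd[j]
    if add_intercept:
        amat[0, 0] = 1.0
        for j in range(1, p):
            amat[0, j] = -col_mean[j] / col_sd[j]
    beta = amat @ theta[:-1] if add_intercept else theta[:-1] / col_sd
    re_sd = float(np.exp(theta[-1]))

    if compute_se:
        # Hessian as centered finite differences of the analytic gradient
        with np.errstate(all="ignore"):
            h = approx_fprime(theta, grad, centered=True)
            h = 0.5 * (h + h.T)
        try:
            cov_std = np.linalg.inv(h)[:p, :p]
            cov = amat @ cov_std @ amat.T if add_intercept else \
                cov_std / np.outer(col_sd, col_sd)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    else:
        se = np.full(p, np.nan)
    return GlmmFit(
        terms=terms,
        params=pd.Series(beta, index=terms),
        se=pd.Series(se, index=terms),
        re_sd=re_sd,
        loglik=loglik,
        k=len(terms) + 1,
        n=len(y),
        n_groups=int(n_g),
        converged=bool(res.success),
        name=name,
    )
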