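"""Maximum-likelihood logistic regression with a random intercept.

The victimization model needs a binomial GLMM with a pen random
intercept.  The marginal likelihood integrates the random effect out of
each pen's likelihood,

    L_j(beta, sigma) = int prod_i p_ij(u)^y_ij (1 - p_ij(u))^(1-y_ij)
                       phi(u; 0, sigma^2) du,
    logit p_ij(u) = x_ij' beta + u,

and is evaluated exactly enough with Gauss-Hermite quadrature (pens are
small, so a modest node count is ample).  Standard errors come from the
numerical Hessian of the negative log likelihood at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit
from statsmodels.tools import numdiff

from .data import ValidationError

__all__ = ["GlmmFit", "fit_logit_random_intercept"]


@dataclass(frozen=True)
class GlmmFit:
    params: np.ndarray  # fixed-effect coefficients
    se: np.ndarray
    sigma_u: float  # random-intercept SD
    llf: float
    aic: float
    converged: bool
    n_groups: int


def _nll_factory(y, X, group_index, n_groups, nodes, weights):
    log_w = np.log(weights / np.sqrt(np.pi))

    def nll(theta: np.ndarray) -> float:
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        eta = X @ beta
        per = np.empty((n_groups, nodes.size))
        for k, xk in enumerate(nodes):
            u = np.sqrt(2.0) * sigma * xk
            p = expit(eta + u)
            lp = y * np.log(p + 1e-300) + (1.0 - y) * np.log(1.0 - p + 1e-300)
            per[:, k] = np.bincount(group_index, weights=lp, minlength=n_groups)
        per += log_w
        m = per.max(axis=1)
        return -float(
            np.sum(np.log(np.sum(np.exp(per - m[:, None]), axis=1)) + m)
        )

    return nll


def fit_logit_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, n_quad: int = 15
) -> GlmmFit:
    """Fit the random-intercept logit by marginal maximum likelihood.

    ``X`` must include the intercept column.  Returns fixed-effect
    estimates with Wald standard errors; the random-intercept SD is
    estimated on the log scale and reported back-transformed.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 1 or X.shape[0] != y.size or groups.size != y.size:
        raise ValidationError("y, X, and groups must align row-wise")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("response must be binary 0/1")
    uniq, group_index = np.unique(groups, return_inverse=True)
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    nll = _nll_factory(y, X, group_index, uniq.size, nodes, weights)
    theta0 = np.zeros(X.shape[1] + 1)
    res = optimize.minimize(nll, theta0, method="BFGS")
    theta = res.x
    hess = numdiff.approx_hess1(theta, nll)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(theta.size, np.nan)
    k = theta.size
    llf = -float(res.fun)
    return GlmmFit(
        params=theta[:-1],
        se=se_all[:-1],
        sigma_u=float(np.exp(theta[-1])),
        llf=llf,
        aic=-2.0 * llf + 2.0 * k,
        converged=bool(res.success),
        n_groups=int(uniq.size),
    )
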