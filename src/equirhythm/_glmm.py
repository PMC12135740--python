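"""Random-intercept GLMM fitting by Gauss-Hermite quadrature.

Maximum-likelihood estimation of a generalised linear mixed model with a
single random intercept per group, for Bernoulli (logit link) and Poisson
(log link) families.  The marginal likelihood integral over the random
intercept is evaluated with Gauss-Hermite quadrature — the standard
approach for random-intercept models — and maximised with scipy's L-BFGS-B.
Wald standard errors come from the numerically differentiated Hessian at
the optimum.

When the estimated random-intercept standard deviation collapses to the
boundary the model degenerates to the pooled GLM; callers are expected to
fall back accordingly (see ``singular``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from statsmodels.tools import numdiff

_LOG_SIGMA_MIN = np.log(1e-6)
_LOG_SIGMA_MAX = np.log(20.0)
_SINGULAR_SD = 1e-3


@dataclass
class RandomInterceptFit:
    beta: np.ndarray
    beta_se: np.ndarray
    sigma: float
    loglike: float
    converged: bool
    singular: bool
    cov: np.ndarray


def _group_loglike(params, y, X, group_idx, n_groups, family, nodes, weights):
    beta = params[:-1]
    sigma = np.exp(params[-1])
    eta0 = X @ beta
    # eta per (obs, node)
    eta = eta0[:, None] + np.sqrt(2.0) * sigma * nodes[None, :]
    if family == "binomial":
        ll_obs = y[:, None] * eta - np.log1p(np.exp(-np.abs(eta))) - np.maximum(eta, 0)
    elif family == "poisson":
        ll_obs = y[:, None] * eta - np.exp(eta) - special.gammaln(y + 1.0)[:, None]
    else:  # pragma: no cover - guarded upstream
        raise ValueError(f"unsupported family {family!r}")
    # sum log-likelihood contributions within group, per node
    ll_group = np.zeros((n_groups, nodes.size))
    np.add.at(ll_group, group_idx, ll_obs)
    log_w = np.log(weights / np.sqrt(np.pi))
    return float(np.sum(special.logsumexp(ll_group + log_w[None, :], axis=1)))


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    family: str = "binomial",
    n_quad: int = 61,
) -> RandomInterceptFit:
    """Fit ``g(E[y]) = X beta + u_group`` with ``u ~ N(0, sigma^2)``."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _, group_idx = np.unique(groups, return_inverse=True)
    n_groups = int(group_idx.max()) + 1
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    p = X.shape[1]

    import statsmodels.api as sm

    fam = sm.families.Binomial() if family == "binomial" else sm.families.Poisson()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start_beta = sm.GLM(y, X, family=fam).fit(maxiter=200).params
    start = np.concatenate([start_beta, [np.log(0.5)]])

    def nll(params):
        return -_group_loglike(
            params, y, X, group_idx, n_groups, family, nodes, weights
        )

    bounds = [(None, None)] * p + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)]
    res = optimize.minimize(
        nll, start, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11},
    )
    params = res.x
    sigma = float(np.exp(params[-1]))
    singular = sigma < _SINGULAR_SD

    if singular:
        beta_se = np.full(p, np.nan)
        cov = np.full((p, p), np.nan)
    else:
        hess = numdiff.approx_hess(params, nll)
        try:
            cov_all = np.linalg.inv(hess)
            cov = cov_all[:p, :p]
            diag = np.diag(cov).copy()
            if np.any(diag <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
            beta_se = np.sqrt(diag)
        except np.linalg.LinAlgError:
            # profile out the variance parameter
            hess_b = numdiff.approx_hess(
                params[:p], lambda b: nll(np.concatenate([b, params[p:]]))
            )
            cov = np.linalg.inv(hess_b)
            beta_se = np.sqrt(np.diag(cov))

    return RandomInterceptFit(
        beta=params[:p],
        beta_se=beta_se,
        sigma=sigma,
        loglike=-float(res.fun),
        converged=bool(res.success),
        singular=singular,
        cov=cov,
    )
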