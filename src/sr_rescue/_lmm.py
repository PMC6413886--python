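"""Random-intercept linear mixed model fitted by profiled maximum likelihood.

The in-vitro screen fits tens of thousands of tiny models of the form

    y ~ X beta + u[group] + eps,   u ~ N(0, s_u^2),  eps ~ N(0, s_e^2)

with a single grouping factor (cancer type).  For this structure the
marginal covariance is block-diagonal with blocks s_e^2 (I + theta J),
theta = s_u^2 / s_e^2, so GLS reduces to per-group mean corrections
((I + theta J)^-1 = I - theta/(1 + theta n_j) J) and the ML log-likelihood
can be profiled down to a 1-D optimization over theta.  This is orders of
magnitude faster than constructing a general mixed-model object per pair
and is cross-checked against statsmodels MixedLM in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

__all__ = ["RandomInterceptFit", "fit_random_intercept", "lrt_random_intercept"]

_LOG2PI = float(np.log(2.0 * np.pi))


class RandomInterceptFit:
    __slots__ = ("beta", "theta", "sigma2", "loglik", "n")

    def __init__(self, beta, theta, sigma2, loglik, n):
        self.beta = beta
        self.theta = theta
        self.sigma2 = sigma2
        self.loglik = loglik
        self.n = n


def _group_blocks(groups):
    """Return (order, boundaries, sizes) so rows sorted by ``order`` form
    contiguous group blocks addressable with np.add.reduceat."""
    codes, _ = _factorize(groups)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.flatnonzero(np.r_[True, sorted_codes[1:] != sorted_codes[:-1]])
    sizes = np.diff(np.r_[starts, sorted_codes.size])
    return order, starts, sizes


def _factorize(groups):
    arr = np.asarray(groups)
    uniq, codes = np.unique(arr, return_inverse=True)
    return codes, uniq


def _profiled_loglik(theta, y, X, starts, sizes):
    """ML log-likelihood with sigma2 profiled out, at variance ratio theta."""
    n = y.size
    # c_j = theta / (1 + theta * n_j) per group
    c = theta / (1.0 + theta * sizes)
    # V^{-1} A = A - c_j * 1 (1^T A) within group, done via reduceat sums
    ysum = np.add.reduceat(y, starts)
    Xsum = np.add.reduceat(X, starts, axis=0)
    # X^T V^{-1} X = X^T X - sum_j c_j Xsum_j Xsum_j^T
    XtX = X.T @ X - (Xsum.T * c) @ Xsum
    Xty = X.T @ y - (Xsum.T * c) @ ysum
    yty = y @ y - c @ (ysum**2)
    try:
        beta = np.linalg.solve(XtX, Xty)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    rss = yty - beta @ Xty  # y^T V^-1 y - beta^T X^T V^-1 y
    if rss <= 0:
        return -np.inf, None, None
    sigma2 = rss / n
    logdet = float(np.sum(np.log1p(theta * sizes)))
    ll = -0.5 * (n * (_LOG2PI + np.log(sigma2) + 1.0) + logdet)
    return ll, beta, sigma2


def fit_random_intercept(y, X, groups) -> RandomInterceptFit:
    """Maximize the profiled ML over theta >= 0.

    y: response vector; X: design matrix (include the intercept column);
    groups: group label per observation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    order, starts, sizes = _group_blocks(groups)
    ys, Xs = y[order], X[order]

    def neg_ll(log_theta):
        ll, _, _ = _profiled_loglik(np.exp(log_theta), ys, Xs, starts, sizes)
        return -ll

    ll0, beta0, s20 = _profiled_loglik(0.0, ys, Xs, starts, sizes)
    best = (ll0, 0.0, beta0, s20)
    if len(sizes) > 1:
        res = minimize_scalar(neg_ll, bounds=(-10.0, 10.0), method="bounded",
                              options={"xatol": 1e-6})
        theta = float(np.exp(res.x))
        ll, beta, s2 = _profiled_loglik(theta, ys, Xs, starts, sizes)
        if ll > best[0]:
            best = (ll, theta, beta, s2)
    ll, theta, beta, s2 = best
    if beta is None:
        raise np.linalg.LinAlgError("singular mixed-model design")
    return RandomInterceptFit(beta, theta, s2, ll, y.size)


def lrt_random_intercept(y, x, groups):
    """Slope and 1-df likelihood-ratio p-value for the fixed effect of x in
    y ~ 1 + x + (1 | group), both models fitted by ML.

    Returns (beta_x, p).  Raises ValueError on a constant covariate.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("constant covariate: slope undefined")
    ones = np.ones_like(y)
    full = fit_random_intercept(y, np.column_stack([ones, x]), groups)
    null = fit_random_intercept(y, ones[:, None], groups)
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = float(chi2.sf(stat, df=1))
    return float(full.beta[1]), p
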