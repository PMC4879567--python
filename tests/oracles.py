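"""Independent brute-force oracles used by the tests.

Everything here assembles the joint Gaussian distribution of states and
observations element-wise and conditions densely — no Kalman recursions —
so it can serve as an independent check of the filter/smoother at small n.
"""

import numpy as np
from scipy import stats

from ssmdiag import SSMParams


def dense_moments(params: SSMParams, n: int):
    """Mean/covariance of (x_1..x_n, y_1..y_n) under the model."""
    rho = params.rho
    ve = params.sigma_eta ** 2
    vh = params.sigma_eps ** 2
    if params.x0_prior is None:
        m0, v0 = params.x0, 0.0
    else:
        m0, v0 = params.x0_prior.mu, params.x0_prior.sigma0 ** 2
    mx = m0 * rho ** np.arange(1, n + 1)
    var = np.empty(n)
    var[0] = rho * rho * v0 + ve
    for t in range(1, n):
        var[t] = rho * rho * var[t - 1] + ve
    cx = np.empty((n, n))
    for s in range(n):
        for t in range(s, n):
            cx[s, t] = cx[t, s] = rho ** (t - s) * var[s]
    cy = cx + vh * np.eye(n)
    return mx, cx, cy


def dense_loglik(params: SSMParams, y: np.ndarray) -> float:
    """Log density of the observed entries of y under the joint Gaussian."""
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    if obs.sum() == 0:
        return 0.0
    mx, _, cy = dense_moments(params, y.size)
    idx = np.flatnonzero(obs)
    mean = mx[idx]
    cov = cy[np.ix_(idx, idx)]
    return float(
        stats.multivariate_normal(mean=mean, cov=cov, allow_singular=True).logpdf(y[idx])
    )


def dense_smooth(params: SSMParams, y: np.ndarray):
    """Conditional mean and variance of each state given the observed y."""
    y = np.asarray(y, dtype=float)
    n = y.size
    mx, cx, cy = dense_moments(params, n)
    obs = np.flatnonzero(~np.isnan(y))
    if obs.size == 0:
        return mx.copy(), np.diag(cx).copy()
    cyo = cy[np.ix_(obs, obs)]
    cxy = cx[:, obs]  # Cov(x_t, y_s) = Cov(x_t, x_s) for observed s
    sol = np.linalg.solve(cyo, y[obs] - mx[obs])
    mean = mx + cxy @ sol
    cov_red = cxy @ np.linalg.solve(cyo, cxy.T)
    var = np.diag(cx) - np.diag(cov_red)
    return mean, var


def grid_search_loglik(series, fixed_mask, grids) -> float:
    """Best log-likelihood over a coarse parameter grid (crude global check)."""
    from ssmdiag import TimeSeries, kalman_filter_loglik

    best = -np.inf
    for se in grids["sigma_eps"]:
        for r in grids["rho"]:
            for sn in grids["sigma_eta"]:
                vals = {"sigma_eps": se, "rho": r, "sigma_eta": sn}
                vals.update(fixed_mask)
                p = SSMParams(rho=vals["rho"], sigma_eta=vals["sigma_eta"],
                              sigma_eps=vals["sigma_eps"])
                ll = kalman_filter_loglik(p, series).loglik
                best = max(best, ll)
    return best
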