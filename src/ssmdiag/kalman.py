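"""Exact Kalman filtering, RTS smoothing and likelihoods for the
univariate AR(1)-plus-noise state-space model.

The marginal likelihood of the observations (latent states integrated out)
is computed by the prediction-error decomposition, which is exact for linear
Gaussian models.  Missing observations skip the update step and propagate
the one-step prediction, so irregularly observed series are handled
transparently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (
    DegenerateLikelihoodError,
    InvalidConfigError,
    SSMParams,
    TimeSeries,
)

# Variance floor inside the recursions; prevents division blow-ups when an
# optimizer wanders to (numerically) zero variances.
VAR_FLOOR = 1e-12

_LOG_2PI = math.log(2.0 * math.pi)

__all__ = [
    "FilterSmootherOutput",
    "kalman_filter_loglik",
    "kalman_smooth",
    "joint_loglik_known_states",
    "VAR_FLOOR",
]


@dataclass
class FilterSmootherOutput:
    """Per-time-step filter/smoother moments and the marginal log-likelihood.

    All arrays have length n (time steps 1..n).  ``predicted_*`` are the
    one-step-ahead moments E[x_t | y_{1:t-1}], ``filtered_*`` the updated
    moments E[x_t | y_{1:t}] and ``smoothed_*`` the full-information moments
    E[x_t | y_{1:n}] (None until smoothing is run).  ``loglik`` is the total
    marginal log-likelihood of the observed entries, in nats.
    """

    predicted_mean: np.ndarray
    predicted_var: np.ndarray
    filtered_mean: np.ndarray
    filtered_var: np.ndarray
    loglik: float
    smoothed_mean: np.ndarray | None = None
    smoothed_var: np.ndarray | None = None
    n_clipped: int = 0


def _init_moments(params: SSMParams) -> tuple[float, float]:
    if params.x0_prior is None:
        return params.x0, 0.0
    return params.x0_prior.mu, params.x0_prior.sigma0 ** 2


def loglik_scalar(
    y: np.ndarray,
    rho: float,
    var_eta: float,
    var_eps: float,
    a0: float,
    p0: float,
) -> float:
    """Fast scalar-loop marginal log-likelihood (no storage).

    Used in the inner loop of maximum-likelihood fitting; NaN entries of
    ``y`` are treated as missing.
    """
    a = a0
    p = p0
    rho2 = rho * rho
    ll = 0.0
    for yt in y:
        a = rho * a
        p = rho2 * p + var_eta
        if p < VAR_FLOOR:
            p = VAR_FLOOR
        if yt == yt:  # not NaN
            f = p + var_eps
            if f < VAR_FLOOR:
                f = VAR_FLOOR
            v = yt - a
            ll -= 0.5 * (_LOG_2PI + math.log(f) + v * v / f)
            k = p / f
            a += k * v
            p -= k * p
    return ll


def _check_degenerate(params: SSMParams, series: TimeSeries) -> None:
    """Raise if both variances are zero with known x0 and the data are
    inconsistent with the resulting deterministic path."""
    if params.sigma_eta == 0.0 and params.sigma_eps == 0.0 and params.x0_prior is None:
        t = np.arange(1, series.n + 1)
        path = params.x0 * params.rho ** t
        resid = series.y - path
        if np.nanmax(np.abs(resid), initial=0.0) > 1e-9:
            raise DegenerateLikelihoodError(
                "sigma_eta = sigma_eps = 0 with known x0: observations are "
                "inconsistent with the deterministic state path"
            )


def kalman_filter_loglik(params: SSMParams, series: TimeSeries) -> FilterSmootherOutput:
    """Run the Kalman filter and return per-step moments plus the exact
    marginal log-likelihood of the observed data.

    The likelihood equals the log density of the observed entries of y under
    the joint Gaussian distribution implied by ``params`` and the x0
    treatment.  A series with every observation missing has log-likelihood 0
    and the filter reduces to the pure prediction recursion.
    """
    _check_degenerate(params, series)
    n = series.n
    y = series.y
    var_eta = params.sigma_eta ** 2
    var_eps = params.sigma_eps ** 2
    rho = params.rho
    a, p = _init_moments(params)

    pred_m = np.empty(n)
    pred_v = np.empty(n)
    filt_m = np.empty(n)
    filt_v = np.empty(n)
    ll = 0.0
    n_clipped = 0
    for t in range(n):
        a = rho * a
        p = rho * rho * p + var_eta
        if p < VAR_FLOOR:
            p = VAR_FLOOR
            n_clipped += 1
        pred_m[t] = a
        pred_v[t] = p
        yt = y[t]
        if yt == yt:
            f = p + var_eps
            if f < VAR_FLOOR:
                f = VAR_FLOOR
                n_clipped += 1
            v = yt - a
            ll -= 0.5 * (_LOG_2PI + math.log(f) + v * v / f)
            k = p / f
            a += k * v
            p -= k * p
        filt_m[t] = a
        filt_v[t] = p
    return FilterSmootherOutput(
        predicted_mean=pred_m,
        predicted_var=pred_v,
        filtered_mean=filt_m,
        filtered_var=filt_v,
        loglik=ll,
        n_clipped=n_clipped,
    )


def kalman_smooth(params: SSMParams, series: TimeSeries) -> FilterSmootherOutput:
    """Rauch-Tung-Striebel smoother: full-information state means/variances.

    ``smoothed_mean[t]`` equals E[x_t | y_1..y_n], the conditional mean of the
    joint Gaussian; likewise for the variances.
    """
    out = kalman_filter_loglik(params, series)
    n = series.n
    rho = params.rho
    sm = np.empty(n)
    sv = np.empty(n)
    sm[n - 1] = out.filtered_mean[n - 1]
    sv[n - 1] = out.filtered_var[n - 1]
    for t in range(n - 2, -1, -1):
        c = out.filtered_var[t] * rho / out.predicted_var[t + 1]
        sm[t] = out.filtered_mean[t] + c * (sm[t + 1] - out.predicted_mean[t + 1])
        sv[t] = out.filtered_var[t] + c * c * (sv[t + 1] - out.predicted_var[t + 1])
        if sv[t] < 0.0:
            sv[t] = 0.0
    out.smoothed_mean = sm
    out.smoothed_var = sv
    return out


def _gauss_logpdf_sum(resid: np.ndarray, sd: float) -> float:
    """Sum of centred Gaussian log densities, treating sd == 0 as a point
    mass: 0 if all residuals vanish, -inf otherwise."""
    if sd == 0.0:
        if resid.size == 0 or np.max(np.abs(resid)) <= 1e-12:
            return 0.0
        return -math.inf
    var = sd * sd
    return float(-0.5 * np.sum(_LOG_2PI + math.log(var) + resid ** 2 / var))


def joint_loglik_known_states(
    params: SSMParams, states: np.ndarray, series: TimeSeries
) -> float:
    """Complete-data log-likelihood with the latent states treated as known.

    Returns sum_t log N(x_t; rho x_{t-1}, sigma_eta^2) over t = 1..n (x_0
    taken from ``params``) plus sum_t log N(y_t; x_t, sigma_eps^2) over the
    non-missing observations.  A zero standard deviation with a non-zero
    residual yields -inf (degenerate-likelihood flag).
    """
    states = np.asarray(states, dtype=float)
    if states.shape != series.y.shape:
        raise InvalidConfigError("states must have the same length as y")
    if np.isnan(states).any():
        raise InvalidConfigError("states must be complete (no missing values)")
    x0 = params.x0 if params.x0_prior is None else params.x0_prior.mu
    x_prev = np.concatenate(([x0], states[:-1]))
    proc_resid = states - params.rho * x_prev
    obs = series.observed
    obs_resid = series.y[obs] - states[obs]
    ll = _gauss_logpdf_sum(proc_resid, params.sigma_eta)
    ll += _gauss_logpdf_sum(obs_resid, params.sigma_eps)
    return ll
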