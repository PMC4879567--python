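"""Maximum-likelihood estimation and estimability diagnostics for the
AR(1)-plus-noise state-space model.

Estimation maximizes the exact marginal likelihood (Kalman prediction-error
decomposition) over theta = (sigma_eps, rho, sigma_eta) on a transformed
scale — log standard deviations, unconstrained rho — so that boundary
estimates (variances collapsing to zero) show up as very negative log-SDs
and are flagged.  Fits are multi-start by default because the likelihood of
this model is often flat, bimodal or jagged when measurement error dominates
process stochasticity.

Diagnostics: Wald intervals from the inverse observed Fisher information,
profile likelihoods with flat-segment and multi-modality detection, 2-D
profile surfaces, parametric-bootstrap intervals, and complete-data fits
with the states held at their true (simulated) values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats

from .kalman import (
    joint_loglik_known_states,
    kalman_smooth,
    loglik_scalar,
)
from .model import GaussianPrior, InvalidConfigError, SSMParams, TimeSeries

PARAM_NAMES = ("sigma_eps", "rho", "sigma_eta")

_CHI2_1 = stats.chi2(df=1)

__all__ = [
    "PARAM_NAMES",
    "FitOptions",
    "FitResult",
    "ProfileResult",
    "SurfaceResult",
    "BootstrapResult",
    "fit_mle",
    "fit_known_states",
    "wald_ci",
    "profile_likelihood",
    "profile_known_states",
    "likelihood_surface",
    "parametric_bootstrap",
]


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for :func:`fit_mle`.

    ``extra_starts`` are additional start points (dicts over the free
    parameters, natural scale) appended to the three default moment-based
    starts.  ``interior_only`` activates interior-solution screening: among
    the per-start solutions, boundary solutions are discarded when at least
    one interior solution exists, even if a boundary solution has the higher
    likelihood.  ``boundary_rel`` sets the boundary threshold for a standard
    deviation estimate as a fraction of sd(y).
    """

    extra_starts: tuple = ()
    interior_only: bool = False
    compute_se: bool = True
    maxiter: int = 300
    gtol: float = 1e-6
    boundary_rel: float = 1e-4
    rho_bounds: tuple = (-2.0, 2.0)


DEFAULT_OPTIONS = FitOptions()


@dataclass
class FitResult:
    """Result of a (possibly constrained) maximum-likelihood fit."""

    theta_hat: dict
    se: dict
    ci_low: dict
    ci_high: dict
    loglik_max: float
    converged: bool
    boundary_flags: dict
    fixed_mask: dict
    starts_used: list
    best_start_index: int
    params_hat: SSMParams

    @property
    def free_names(self) -> tuple:
        return tuple(p for p in PARAM_NAMES if p not in self.fixed_mask)


@dataclass
class ProfileResult:
    """One-dimensional profile likelihood along a focal parameter."""

    focal: str
    grid: np.ndarray
    profile_loglik: np.ndarray
    loglik_max: float
    flat_segments: list
    n_local_maxima: int
    profile_ci: np.ndarray
    valid: np.ndarray

    @property
    def is_multimodal(self) -> bool:
        return self.n_local_maxima >= 2

    @property
    def has_flat_segment(self) -> bool:
        return len(self.flat_segments) > 0


@dataclass
class SurfaceResult:
    """Two-dimensional profile log-likelihood surface."""

    param_a: str
    param_b: str
    grid_a: np.ndarray
    grid_b: np.ndarray
    values: np.ndarray  # shape (len(grid_a), len(grid_b))


@dataclass
class BootstrapResult:
    """Parametric-bootstrap distributions and percentile intervals."""

    thetas: dict
    ci_low: dict
    ci_high: dict
    n_failed: int
    state_ci_low: np.ndarray | None = None
    state_ci_high: np.ndarray | None = None


# ---------------------------------------------------------------------------
# transformed scale


def _free_names(fixed_mask: dict) -> tuple:
    return tuple(p for p in PARAM_NAMES if p not in fixed_mask)


def _encode(values: dict, free: tuple) -> np.ndarray:
    z = np.empty(len(free))
    for i, name in enumerate(free):
        v = values[name]
        if name == "rho":
            z[i] = v
        else:
            z[i] = math.log(max(v, 1e-300))
    return z


def _decode(z: np.ndarray, free: tuple) -> dict:
    out = {}
    for i, name in enumerate(free):
        out[name] = z[i] if name == "rho" else math.exp(z[i])
    return out


def _data_scale(series: TimeSeries) -> float:
    obs = series.y[series.observed]
    if obs.size >= 2:
        s = float(np.std(obs, ddof=1))
    else:
        s = 0.0
    return s if s > 0 else 1.0


def _moment_starts(series: TimeSeries) -> list:
    """Three default start points: moment-based, low measurement error,
    low process noise (all sharing the lag-1-autocorrelation rho start)."""
    y = series.y
    obs = series.observed
    sd_y = _data_scale(series)
    var_y = sd_y * sd_y
    pair = obs[:-1] & obs[1:]
    if pair.sum() >= 3:
        a = y[:-1][pair]
        b = y[1:][pair]
        denom = np.std(a) * np.std(b)
        r1 = float(np.mean((a - a.mean()) * (b - b.mean())) / denom) if denom > 0 else 0.0
    else:
        r1 = 0.0
    r1 = float(np.clip(r1, -0.95, 0.95))
    half = math.sqrt(var_y / 2.0)
    return [
        {"sigma_eps": half, "rho": r1, "sigma_eta": half},
        {"sigma_eps": 0.05 * sd_y, "rho": r1, "sigma_eta": sd_y},
        {"sigma_eps": sd_y, "rho": r1, "sigma_eta": 0.05 * sd_y},
    ]


def _make_objective(series: TimeSeries, fixed_mask: dict, x0: float,
                    x0_prior: GaussianPrior | None):
    free = _free_names(fixed_mask)
    y = series.y
    if x0_prior is None:
        a0, p0 = x0, 0.0
    else:
        a0, p0 = x0_prior.mu, x0_prior.sigma0 ** 2

    def negloglik(z: np.ndarray) -> float:
        vals = dict(fixed_mask)
        vals.update(_decode(z, free))
        ll = loglik_scalar(
            y, vals["rho"], vals["sigma_eta"] ** 2, vals["sigma_eps"] ** 2, a0, p0
        )
        if not math.isfinite(ll):
            return 1e12
        return -ll

    return negloglik, free, (a0, p0)


def _numeric_hessian(fun, z: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    k = z.size
    h = rel_step * np.maximum(1.0, np.abs(z))
    H = np.empty((k, k))
    f0 = fun(z)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (fun(z + ei) - 2.0 * f0 + fun(z - ei)) / (h[i] ** 2)
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            fpp = fun(z + ei + ej)
            fpm = fun(z + ei - ej)
            fmp = fun(z - ei + ej)
            fmm = fun(z - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _se_from_hessian(negloglik, z_hat: np.ndarray, free: tuple, values: dict) -> dict:
    """Delta-method natural-scale standard errors from the transformed-scale
    observed Fisher information; NaN where the Hessian is not positive
    definite (CI then marked unavailable)."""
    se = {name: math.nan for name in free}
    if len(free) == 0:
        return se
    try:
        H = _numeric_hessian(negloglik, z_hat)
        eigvals = np.linalg.eigvalsh(H)
        if np.all(eigvals > 0):
            cov = np.linalg.inv(H)
            sd_z = np.sqrt(np.diag(cov))
            for i, name in enumerate(free):
                se[name] = float(sd_z[i] if name == "rho" else values[name] * sd_z[i])
    except (np.linalg.LinAlgError, ValueError):
        pass
    return se


def _boundary_flags(values: dict, threshold: float) -> dict:
    flags = {}
    for name in PARAM_NAMES:
        if name == "rho":
            flags[name] = False
        else:
            flags[name] = bool(values[name] < threshold)
    return flags


def _boundary_flags_ll(
    negloglik,
    values: dict,
    free: tuple,
    threshold: float,
    nll_best: float,
    ll_tol: float = 0.01,
) -> dict:
    """Boundary detection for the SD parameters.

    A standard deviation is flagged as a boundary estimate when it is below
    the hard threshold, or when collapsing it to (numerically) zero while
    holding the other estimates changes the log-likelihood by less than
    ``ll_tol`` nats — i.e. the likelihood cannot distinguish the estimate
    from zero.  The likelihood check is needed because in the flat region a
    gradient-based optimizer legitimately stops at small but non-tiny values.
    """
    flags = {n: False for n in PARAM_NAMES}
    for name in ("sigma_eps", "sigma_eta"):
        if values[name] < threshold:
            flags[name] = True
        elif name in free:
            probed = dict(values)
            probed[name] = threshold * 1e-2
            z = _encode(probed, free)
            if negloglik(z) <= nll_best + ll_tol:
                flags[name] = True
    return flags


def _assemble_ci(theta: dict, se: dict, level: float = 0.95) -> tuple:
    zq = stats.norm.ppf(0.5 * (1.0 + level))
    lo, hi = {}, {}
    for name in PARAM_NAMES:
        s = se.get(name, 0.0)
        if not math.isfinite(s):
            lo[name] = math.nan
            hi[name] = math.nan
        else:
            lo[name] = theta[name] - zq * s
            hi[name] = theta[name] + zq * s
    return lo, hi


# ---------------------------------------------------------------------------
# fitting


def fit_mle(
    series: TimeSeries,
    fixed_mask: dict | None = None,
    x0: float = 0.0,
    x0_prior: GaussianPrior | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Maximize the exact marginal likelihood over the free parameters.

    ``fixed_mask`` maps parameter names (``sigma_eps``, ``rho``,
    ``sigma_eta``) to values held fixed during optimization.  All configured
    starts are run; the best solution is returned (or, with
    ``options.interior_only``, the best interior solution when one exists).
    Optimizer failure at every start is reported via ``converged=False``,
    never as an exception.
    """
    fixed_mask = dict(fixed_mask or {})
    options = options or DEFAULT_OPTIONS
    for name in fixed_mask:
        if name not in PARAM_NAMES:
            raise InvalidConfigError(f"unknown parameter {name!r}")
    negloglik, free, _ = _make_objective(series, fixed_mask, x0, x0_prior)
    sd_y = _data_scale(series)
    threshold = options.boundary_rel * sd_y
    x0_spec = {"x0": x0, "x0_prior": x0_prior}

    if len(free) == 0:
        theta = {n: float(fixed_mask[n]) for n in PARAM_NAMES}
        ll = -negloglik(np.empty(0))
        se = {n: 0.0 for n in PARAM_NAMES}
        lo, hi = _assemble_ci(theta, se)
        return FitResult(
            theta_hat=theta,
            se=se,
            ci_low=lo,
            ci_high=hi,
            loglik_max=ll,
            converged=True,
            boundary_flags=_boundary_flags(theta, threshold),
            fixed_mask=fixed_mask,
            starts_used=[],
            best_start_index=-1,
            params_hat=SSMParams(
                rho=theta["rho"],
                sigma_eta=theta["sigma_eta"],
                sigma_eps=theta["sigma_eps"],
                **x0_spec,
            ),
        )

    if series.n_observed < 3:
        raise InvalidConfigError("need at least 3 non-missing observations")

    starts = _moment_starts(series) + [dict(s) for s in options.extra_starts]
    bounds = []
    for name in free:
        if name == "rho":
            bounds.append(options.rho_bounds)
        else:
            bounds.append((math.log(sd_y) - 20.0, math.log(sd_y) + 5.0))

    solutions = []
    for start in starts:
        z0 = _encode({**start, **fixed_mask}, free)
        z0 = np.clip(z0, [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            res = optimize.minimize(
                negloglik,
                z0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": options.maxiter, "gtol": options.gtol,
                         "ftol": 1e-12},
            )
            solutions.append((-res.fun, res.x, bool(res.success)))
        except (ValueError, FloatingPointError):
            solutions.append((-math.inf, z0, False))

    lls = [s[0] for s in solutions]
    best_idx = int(np.argmax(lls))
    if options.interior_only:
        interior = []
        for i, (ll_i, z_i, _ok) in enumerate(solutions):
            vals_i = dict(fixed_mask)
            vals_i.update(_decode(z_i, free))
            flags_i = _boundary_flags_ll(negloglik, vals_i, free, threshold, -ll_i)
            if not any(flags_i[n] for n in free if n != "rho"):
                interior.append(i)
        if interior:
            best_idx = max(interior, key=lambda i: lls[i])

    ll_best, z_best, success = solutions[best_idx]
    values = dict(fixed_mask)
    values.update(_decode(z_best, free))
    theta = {n: float(values[n]) for n in PARAM_NAMES}

    se = {n: 0.0 for n in PARAM_NAMES}
    if options.compute_se:
        se_free = _se_from_hessian(negloglik, z_best, free, values)
        se.update(se_free)
    else:
        se.update({n: math.nan for n in free})
    lo, hi = _assemble_ci(theta, se)

    converged = bool(success) and math.isfinite(ll_best)
    return FitResult(
        theta_hat=theta,
        se=se,
        ci_low=lo,
        ci_high=hi,
        loglik_max=float(ll_best),
        converged=converged,
        boundary_flags=_boundary_flags_ll(negloglik, values, free, threshold, -ll_best),
        fixed_mask=fixed_mask,
        starts_used=starts,
        best_start_index=best_idx,
        params_hat=SSMParams(
            rho=theta["rho"],
            sigma_eta=theta["sigma_eta"],
            sigma_eps=theta["sigma_eps"],
            **x0_spec,
        ),
    )


def fit_known_states(
    series: TimeSeries,
    states: np.ndarray,
    x0: float = 0.0,
    options: FitOptions | None = None,
) -> FitResult:
    """Complete-data fit: maximize the joint likelihood with the latent
    states held at their (simulated) values.

    The maximizer has closed form: rho_hat is the least-squares AR(1)
    coefficient of the state path, sigma_eta_hat the residual SD of the
    process equation and sigma_eps_hat the SD of the observation residuals
    y_t - x_t over non-missing days.
    """
    options = options or DEFAULT_OPTIONS
    states = np.asarray(states, dtype=float)
    if states.shape != series.y.shape:
        raise InvalidConfigError("states must have the same length as y")
    x_prev = np.concatenate(([x0], states[:-1]))
    denom = float(np.dot(x_prev, x_prev))
    rho_hat = float(np.dot(x_prev, states) / denom) if denom > 0 else 0.0
    sigma_eta_hat = float(np.sqrt(np.mean((states - rho_hat * x_prev) ** 2)))
    obs = series.observed
    if obs.sum() == 0:
        sigma_eps_hat = 0.0
    else:
        sigma_eps_hat = float(np.sqrt(np.mean((series.y[obs] - states[obs]) ** 2)))
    theta = {"sigma_eps": sigma_eps_hat, "rho": rho_hat, "sigma_eta": sigma_eta_hat}
    params = SSMParams(rho=rho_hat, sigma_eta=sigma_eta_hat, sigma_eps=sigma_eps_hat, x0=x0)
    ll = joint_loglik_known_states(params, states, series)

    free = PARAM_NAMES
    sd_y = _data_scale(series)
    threshold = options.boundary_rel * sd_y

    def negjoint(z: np.ndarray) -> float:
        vals = _decode(z, free)
        p = SSMParams(
            rho=vals["rho"],
            sigma_eta=vals["sigma_eta"],
            sigma_eps=vals["sigma_eps"],
            x0=x0,
        )
        v = joint_loglik_known_states(p, states, series)
        return -v if math.isfinite(v) else 1e12

    se = {n: math.nan for n in PARAM_NAMES}
    if options.compute_se and sigma_eps_hat > 0 and sigma_eta_hat > 0:
        z_hat = _encode(theta, free)
        se = _se_from_hessian(negjoint, z_hat, free, theta)
    lo, hi = _assemble_ci(theta, se)
    return FitResult(
        theta_hat=theta,
        se=se,
        ci_low=lo,
        ci_high=hi,
        loglik_max=float(ll),
        converged=True,
        boundary_flags=_boundary_flags(theta, threshold),
        fixed_mask={},
        starts_used=[dict(theta)],
        best_start_index=0,
        params_hat=params,
    )


def wald_ci(fit: FitResult, level: float = 0.95) -> dict:
    """Wald intervals estimate +/- z * se on the reporting (natural) scale.

    Parameters with non-finite standard errors get (nan, nan) — the interval
    is unavailable.  A zero standard error degenerates to the point estimate.
    """
    zq = float(stats.norm.ppf(0.5 * (1.0 + level)))
    out = {}
    for name in PARAM_NAMES:
        est = fit.theta_hat[name]
        s = fit.se.get(name, math.nan)
        if not math.isfinite(s):
            out[name] = (math.nan, math.nan)
        else:
            out[name] = (est - zq * s, est + zq * s)
    return out


# ---------------------------------------------------------------------------
# profiles and surfaces


def _flat_segments(grid: np.ndarray, ll: np.ndarray, tol: float, min_frac: float) -> list:
    """Maximal contiguous grid stretches over which the profile varies by
    less than ``tol`` nats and that span at least ``min_frac`` of the grid."""
    n = len(grid)
    min_len = max(2, int(math.ceil(min_frac * n)))
    segments = []
    i = 0
    while i < n:
        j = i
        lo = hi = ll[i]
        while j + 1 < n:
            nlo = min(lo, ll[j + 1])
            nhi = max(hi, ll[j + 1])
            if nhi - nlo < tol:
                lo, hi = nlo, nhi
                j += 1
            else:
                break
        if j - i + 1 >= min_len:
            segments.append((float(grid[i]), float(grid[j])))
            i = j + 1
        else:
            i += 1
    return segments


def _count_local_maxima(ll: np.ndarray, prominence: float) -> int:
    if len(ll) < 2:
        return min(len(ll), 1)
    padded = np.concatenate(([-np.inf], ll, [-np.inf]))
    peaks, _ = signal.find_peaks(padded, prominence=prominence)
    return int(len(peaks))


def _finish_profile(
    focal: str,
    grid: np.ndarray,
    ll: np.ndarray,
    loglik_max: float,
    level: float,
    flat_tol: float,
    flat_min_frac: float,
    prominence: float,
) -> ProfileResult:
    valid = np.isfinite(ll)
    gv = grid[valid]
    lv = ll[valid]
    if lv.size:
        overall = max(loglik_max, float(np.max(lv)))
        cutoff = overall - 0.5 * float(_CHI2_1.ppf(level))
        ci = gv[lv >= cutoff]
        flats = _flat_segments(gv, lv, flat_tol, flat_min_frac)
        nmax = _count_local_maxima(lv, prominence)
    else:
        overall, ci, flats, nmax = loglik_max, np.empty(0), [], 0
    return ProfileResult(
        focal=focal,
        grid=np.asarray(grid, dtype=float),
        profile_loglik=ll,
        loglik_max=overall,
        flat_segments=flats,
        n_local_maxima=nmax,
        profile_ci=np.asarray(ci, dtype=float),
        valid=valid,
    )


def profile_likelihood(
    series: TimeSeries,
    focal: str,
    grid,
    fixed_mask: dict | None = None,
    x0: float = 0.0,
    x0_prior: GaussianPrior | None = None,
    options: FitOptions | None = None,
    level: float = 0.95,
    flat_tol: float = 0.05,
    flat_min_frac: float = 0.2,
    prominence: float = 0.05,
) -> ProfileResult:
    """Profile the marginal likelihood along ``focal``.

    Each grid point re-optimizes the remaining free parameters (multi-start).
    Flat segments (range < ``flat_tol`` nats over >= ``flat_min_frac`` of the
    grid) and multiple local maxima (prominence > ``prominence`` nats) are
    flagged — the signatures of an estimability problem.
    """
    if focal not in PARAM_NAMES:
        raise InvalidConfigError(f"unknown parameter {focal!r}")
    fixed_mask = dict(fixed_mask or {})
    grid = np.asarray(grid, dtype=float)
    base = fit_mle(
        series,
        fixed_mask,
        x0=x0,
        x0_prior=x0_prior,
        options=FitOptions(
            extra_starts=(options or DEFAULT_OPTIONS).extra_starts,
            interior_only=(options or DEFAULT_OPTIONS).interior_only,
            compute_se=False,
        ),
    )
    ll = np.full(grid.shape, np.nan)
    for i, g in enumerate(grid):
        fm = dict(fixed_mask)
        fm[focal] = float(g)
        try:
            fit = fit_mle(
                series,
                fm,
                x0=x0,
                x0_prior=x0_prior,
                options=FitOptions(compute_se=False),
            )
            ll[i] = fit.loglik_max
        except InvalidConfigError:
            pass
    return _finish_profile(
        focal, grid, ll, base.loglik_max, level, flat_tol, flat_min_frac, prominence
    )


def profile_known_states(
    series: TimeSeries,
    states: np.ndarray,
    focal: str,
    grid,
    x0: float = 0.0,
    level: float = 0.95,
    flat_tol: float = 0.05,
    flat_min_frac: float = 0.2,
    prominence: float = 0.05,
) -> ProfileResult:
    """Profile of the complete-data (known-states) likelihood along
    ``focal``; the nuisance maximizations have closed forms."""
    if focal not in PARAM_NAMES:
        raise InvalidConfigError(f"unknown parameter {focal!r}")
    states = np.asarray(states, dtype=float)
    grid = np.asarray(grid, dtype=float)
    base = fit_known_states(series, states, x0=x0, options=FitOptions(compute_se=False))
    x_prev = np.concatenate(([x0], states[:-1]))
    obs = series.observed
    obs_resid = series.y[obs] - states[obs]
    denom = float(np.dot(x_prev, x_prev))
    rho_ols = float(np.dot(x_prev, states) / denom) if denom > 0 else 0.0

    ll = np.full(grid.shape, np.nan)
    for i, g in enumerate(grid):
        theta = dict(base.theta_hat)
        if focal == "rho":
            theta["rho"] = float(g)
            theta["sigma_eta"] = float(
                np.sqrt(np.mean((states - g * x_prev) ** 2))
            )
        elif focal == "sigma_eta":
            theta["sigma_eta"] = float(g)
            theta["rho"] = rho_ols
        else:
            theta["sigma_eps"] = float(g)
        p = SSMParams(
            rho=theta["rho"],
            sigma_eta=theta["sigma_eta"],
            sigma_eps=theta["sigma_eps"],
            x0=x0,
        )
        v = joint_loglik_known_states(p, states, series)
        if math.isfinite(v):
            ll[i] = v
    return _finish_profile(
        focal, grid, ll, base.loglik_max, level, flat_tol, flat_min_frac, prominence
    )


def likelihood_surface(
    series: TimeSeries,
    param_a: str,
    param_b: str,
    grid_a,
    grid_b,
    fixed_mask: dict | None = None,
    x0: float = 0.0,
    x0_prior: GaussianPrior | None = None,
) -> SurfaceResult:
    """Profile log-likelihood over a 2-D parameter grid.

    Each cell fixes (param_a, param_b) and re-optimizes any remaining free
    parameter; a ridge of near-constant values along a trade-off curve is the
    classic symptom of a parameter-identifiability problem.
    """
    if param_a == param_b:
        raise InvalidConfigError("param_a and param_b must differ")
    fixed_mask = dict(fixed_mask or {})
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    values = np.full((grid_a.size, grid_b.size), np.nan)
    for i, ga in enumerate(grid_a):
        for j, gb in enumerate(grid_b):
            fm = dict(fixed_mask)
            fm[param_a] = float(ga)
            fm[param_b] = float(gb)
            try:
                fit = fit_mle(
                    series,
                    fm,
                    x0=x0,
                    x0_prior=x0_prior,
                    options=FitOptions(compute_se=False),
                )
                values[i, j] = fit.loglik_max
            except InvalidConfigError:
                pass
    return SurfaceResult(
        param_a=param_a,
        param_b=param_b,
        grid_a=grid_a,
        grid_b=grid_b,
        values=values,
    )


# ---------------------------------------------------------------------------
# parametric bootstrap


def parametric_bootstrap(
    fit: FitResult,
    series_length: int,
    B: int,
    seed: int,
    series: TimeSeries | None = None,
    options: FitOptions | None = None,
    level: float = 0.95,
) -> BootstrapResult:
    """Parametric-bootstrap percentile intervals for parameters (and,
    optionally, states).

    Simulates ``B`` series of length ``series_length`` at the fitted
    parameters, refits each with the same fixed-parameter mask, and returns
    the (1-level)/2 and (1+level)/2 quantiles of the refitted estimates.
    When the original ``series`` is supplied, state intervals are the same
    quantiles of its smoothed state path evaluated under each bootstrap
    parameter draw.  Failed refits are dropped and counted.
    """
    from .simulate import simulate_ssm  # local import to avoid a cycle

    if B < 1:
        raise InvalidConfigError("B must be >= 1")
    if not fit.converged:
        raise InvalidConfigError("parametric bootstrap requires a converged fit")
    params = fit.params_hat
    draws = {n: [] for n in PARAM_NAMES}
    states = []
    n_failed = 0
    for b in range(B):
        sim = simulate_ssm(params, series_length, seed + b)
        try:
            refit = fit_mle(
                sim,
                fit.fixed_mask,
                x0=params.x0,
                x0_prior=params.x0_prior,
                options=FitOptions(compute_se=False),
            )
        except InvalidConfigError:
            n_failed += 1
            continue
        if not math.isfinite(refit.loglik_max):
            n_failed += 1
            continue
        for n in PARAM_NAMES:
            draws[n].append(refit.theta_hat[n])
        if series is not None:
            states.append(kalman_smooth(refit.params_hat, series).smoothed_mean)
    if not draws["rho"]:
        raise InvalidConfigError("every bootstrap refit failed")
    qlo, qhi = 50.0 * (1.0 - level), 50.0 * (1.0 + level)
    thetas = {n: np.asarray(v) for n, v in draws.items()}
    ci_low = {n: float(np.percentile(v, qlo)) for n, v in thetas.items()}
    ci_high = {n: float(np.percentile(v, qhi)) for n, v in thetas.items()}
    s_lo = s_hi = None
    if series is not None and states:
        arr = np.asarray(states)
        s_lo = np.percentile(arr, qlo, axis=0)
        s_hi = np.percentile(arr, qhi, axis=0)
    return BootstrapResult(
        thetas=thetas,
        ci_low=ci_low,
        ci_high=ci_high,
        n_failed=n_failed,
        state_ci_low=s_lo,
        state_ci_high=s_hi,
    )
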