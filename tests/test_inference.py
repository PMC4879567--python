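"""Maximum-likelihood fitting, intervals, profiles and bootstrap."""

import math

import numpy as np
import pytest

import ssmdiag as sd
from ssmdiag.inference import _make_objective
from scipy import optimize

from oracles import grid_search_loglik


class TestFitMLE:
    def test_fully_fixed_mask_identity(self, study_params, short_series):
        fm = {"sigma_eps": 0.1, "rho": 0.7, "sigma_eta": 0.2}
        fit = sd.fit_mle(short_series, fixed_mask=fm)
        assert fit.theta_hat == fm
        ll = sd.kalman_filter_loglik(study_params, short_series).loglik
        assert fit.loglik_max == pytest.approx(ll, abs=1e-10)

    def test_consistency_well_identified(self):
        """At n=5000 with measurement error half the process SD, all three
        MLEs land within 0.05 of truth."""
        p = sd.SSMParams(rho=0.7, sigma_eta=1.0, sigma_eps=0.5)
        ts = sd.simulate_ssm(p, 5000, seed=2)
        fit = sd.fit_mle(ts, options=sd.FitOptions(compute_se=False))
        assert fit.converged
        for name, truth in (("sigma_eps", 0.5), ("rho", 0.7), ("sigma_eta", 1.0)):
            assert abs(fit.theta_hat[name] - truth) < 0.05

    def test_beats_coarse_grid_search(self, short_series):
        fit = sd.fit_mle(short_series, options=sd.FitOptions(compute_se=False))
        grids = {
            "sigma_eps": np.linspace(0.02, 0.4, 8),
            "rho": np.linspace(-0.9, 0.95, 10),
            "sigma_eta": np.linspace(0.02, 0.6, 8),
        }
        assert fit.loglik_max >= grid_search_loglik(short_series, {}, grids) - 1e-6

    def test_loglik_reproducible_at_theta_hat(self, short_series):
        fit = sd.fit_mle(short_series, options=sd.FitOptions(compute_se=False))
        ll = sd.kalman_filter_loglik(fit.params_hat, short_series).loglik
        assert fit.loglik_max == pytest.approx(ll, abs=1e-8)

    def test_adding_starts_never_decreases_loglik(self, short_series):
        base = sd.fit_mle(short_series, options=sd.FitOptions(compute_se=False))
        extra = sd.FitOptions(
            compute_se=False,
            extra_starts=(
                {"sigma_eps": 0.5, "rho": -0.5, "sigma_eta": 0.01},
                {"sigma_eps": 0.01, "rho": 0.9, "sigma_eta": 0.5},
            ),
        )
        more = sd.fit_mle(short_series, options=extra)
        assert more.loglik_max >= base.loglik_max - 1e-9

    def test_fixed_sigma_eps_respected(self, short_series):
        fit = sd.fit_mle(short_series, fixed_mask={"sigma_eps": 0.1},
                         options=sd.FitOptions(compute_se=False))
        assert fit.theta_hat["sigma_eps"] == 0.1
        assert fit.fixed_mask == {"sigma_eps": 0.1}

    def test_too_few_observations_raises(self):
        ts = sd.TimeSeries(y=np.array([1.0, np.nan, np.nan, 2.0]))
        with pytest.raises(sd.InvalidConfigError):
            sd.fit_mle(ts)

    def test_boundary_flag_on_near_zero_measurement_error(self):
        # low process-SD scenario where the global maximum collapses sigma_eps
        p = sd.SSMParams(rho=0.7, sigma_eta=0.01, sigma_eps=0.1)
        flagged = 0
        for seed in range(6):
            ts = sd.simulate_ssm(p, 100, seed=seed)
            fit = sd.fit_mle(ts, options=sd.FitOptions(compute_se=False))
            flagged += fit.boundary_flags["sigma_eps"] or fit.boundary_flags["sigma_eta"]
        assert flagged >= 3  # boundary solutions dominate this regime


class TestFitKnownStates:
    def test_closed_form_matches_formulas(self):
        p = sd.SSMParams(rho=0.7, sigma_eta=0.3, sigma_eps=0.2)
        ts = sd.simulate_ssm(p, 500, seed=21)
        fit = sd.fit_known_states(ts, ts.x_true)
        x = ts.x_true
        x_prev = np.concatenate(([0.0], x[:-1]))
        rho_hat = np.sum(x_prev * x) / np.sum(x_prev**2)
        eps_hat = np.sqrt(np.mean((ts.y - x) ** 2))
        assert fit.theta_hat["rho"] == pytest.approx(rho_hat, abs=1e-6)
        assert fit.theta_hat["sigma_eps"] == pytest.approx(eps_hat, abs=1e-6)

    def test_closed_form_is_the_joint_maximizer(self):
        p = sd.SSMParams(rho=0.5, sigma_eta=0.4, sigma_eps=0.3)
        ts = sd.simulate_ssm(p, 200, seed=8)
        fit = sd.fit_known_states(ts, ts.x_true)
        rng = np.random.default_rng(0)
        for _ in range(50):
            q = sd.SSMParams(
                rho=fit.theta_hat["rho"] + rng.normal(0, 0.05),
                sigma_eta=fit.theta_hat["sigma_eta"] * math.exp(rng.normal(0, 0.05)),
                sigma_eps=fit.theta_hat["sigma_eps"] * math.exp(rng.normal(0, 0.05)),
            )
            assert sd.joint_loglik_known_states(q, ts.x_true, ts) <= fit.loglik_max + 1e-9

    def test_exact_observations_flag_boundary(self):
        p = sd.SSMParams(rho=0.7, sigma_eta=0.3, sigma_eps=0.2)
        ts = sd.simulate_ssm(p, 100, seed=4)
        exact = sd.TimeSeries(y=ts.x_true.copy(), x_true=ts.x_true)
        fit = sd.fit_known_states(exact, exact.x_true)
        assert fit.theta_hat["sigma_eps"] == 0.0
        assert fit.boundary_flags["sigma_eps"]


class TestWaldCI:
    def test_zero_se_degenerates_to_point(self, short_series):
        fit = sd.fit_mle(short_series, fixed_mask={"sigma_eps": 0.1, "rho": 0.7,
                                                   "sigma_eta": 0.2})
        ci = sd.wald_ci(fit)
        for name in ("sigma_eps", "rho", "sigma_eta"):
            assert ci[name] == (fit.theta_hat[name], fit.theta_hat[name])

    def test_standard_normal_quantile(self):
        fit = sd.fit_mle(
            sd.simulate_ssm(sd.SSMParams(rho=0.5, sigma_eta=1, sigma_eps=1), 50, 0),
            options=sd.FitOptions(compute_se=False),
        )
        fit.theta_hat["rho"] = 0.0
        fit.se["rho"] = 1.0
        lo, hi = sd.wald_ci(fit, level=0.95)["rho"]
        assert lo == pytest.approx(-1.959964, abs=1e-6)
        assert hi == pytest.approx(1.959964, abs=1e-6)

    def test_ci_brackets_estimate_and_matches_profile_asymptotically(self):
        """At large n the log-likelihood is locally quadratic, so the Wald
        interval for rho agrees closely with the profile interval."""
        p = sd.SSMParams(rho=0.6, sigma_eta=1.0, sigma_eps=0.5)
        ts = sd.simulate_ssm(p, 3000, seed=10)
        fit = sd.fit_mle(ts)
        lo, hi = sd.wald_ci(fit)["rho"]
        assert lo <= fit.theta_hat["rho"] <= hi
        grid = np.linspace(lo - 0.02, hi + 0.02, 41)
        prof = sd.profile_likelihood(ts, "rho", grid)
        assert prof.profile_ci.min() == pytest.approx(lo, abs=0.01)
        assert prof.profile_ci.max() == pytest.approx(hi, abs=0.01)


class TestProfiles:
    def test_profile_at_mle_equals_loglik_max(self, short_series):
        fit = sd.fit_mle(short_series, options=sd.FitOptions(compute_se=False))
        grid = np.array([fit.theta_hat["rho"]])
        prof = sd.profile_likelihood(short_series, "rho", grid)
        assert prof.profile_loglik[0] == pytest.approx(fit.loglik_max, abs=1e-6)

    def test_profile_never_exceeds_unconstrained_max(self, short_series):
        grid = np.linspace(0.2, 0.9, 8)
        prof = sd.profile_likelihood(short_series, "rho", grid)
        assert np.nanmax(prof.profile_loglik) <= prof.loglik_max + 1e-6

    def test_multistart_dominates_single_start(self, short_series):
        """Each profile point is at least as good as a single-start refit."""
        grid = np.linspace(0.01, 0.3, 5)
        prof = sd.profile_likelihood(short_series, "sigma_eps", grid)
        for g, ll in zip(grid, prof.profile_loglik):
            neg, free, _ = _make_objective(short_series, {"sigma_eps": g}, 0.0, None)
            res = optimize.minimize(
                neg, np.array([0.5, math.log(0.2)]), method="L-BFGS-B",
                bounds=[(-2, 2), (-20, 5)],
            )
            assert ll >= -res.fun - 1e-6

    def test_known_states_profile_unimodal(self, study_params):
        ts = sd.simulate_ssm(study_params, 100, seed=12)
        prof = sd.profile_known_states(ts, ts.x_true, "rho",
                                       np.linspace(0.3, 1.0, 41))
        assert prof.n_local_maxima == 1
        assert not prof.has_flat_segment


class TestSurface:
    def test_single_cell_at_mle(self, short_series):
        fit = sd.fit_mle(short_series, options=sd.FitOptions(compute_se=False))
        surf = sd.likelihood_surface(
            short_series, "sigma_eta", "sigma_eps",
            [fit.theta_hat["sigma_eta"]], [fit.theta_hat["sigma_eps"]],
        )
        assert surf.values[0, 0] == pytest.approx(fit.loglik_max, abs=1e-6)

    def test_axis_max_reproduces_1d_profile(self, short_series):
        grid_a = np.linspace(0.1, 0.35, 4)
        grid_b = np.linspace(0.01, 0.25, 7)
        surf = sd.likelihood_surface(short_series, "sigma_eta", "sigma_eps",
                                     grid_a, grid_b)
        prof = sd.profile_likelihood(short_series, "sigma_eta", grid_a)
        col_max = np.nanmax(surf.values, axis=1)
        # the 2-D grid is coarser than the continuous nuisance optimum
        assert np.all(col_max <= prof.profile_loglik + 1e-6)
        assert np.allclose(col_max, prof.profile_loglik, atol=0.3)

    def test_ridge_at_low_process_noise(self):
        """(sigma_eta, sigma_eps) trade off along a near-constant ridge when
        process noise is small — the identifiability signature."""
        p = sd.SSMParams(rho=0.7, sigma_eta=0.01, sigma_eps=0.1)
        ts = sd.simulate_ssm(p, 100, seed=31)
        g = np.linspace(0.005, 0.1, 6)
        surf = sd.likelihood_surface(ts, "sigma_eta", "sigma_eps", g, g)
        best = np.nanmax(surf.values)
        # along the anti-diagonal trade-off curve the surface stays within
        # ~1 nat of the maximum for multiple cells
        near = np.sum(surf.values >= best - 1.0)
        assert near >= 4


class TestParametricBootstrap:
    def test_single_replicate_degenerates(self, short_series):
        fit = sd.fit_mle(short_series, options=sd.FitOptions(compute_se=False))
        boot = sd.parametric_bootstrap(fit, short_series.n, B=1, seed=5)
        for name in ("sigma_eps", "rho", "sigma_eta"):
            assert boot.ci_low[name] == boot.ci_high[name]

    def test_high_signal_coverage(self):
        """Percentile intervals cover the true process SD most of the time
        in the well-identified regime (scaled-down coverage simulation)."""
        p = sd.SSMParams(rho=0.7, sigma_eta=1.0, sigma_eps=0.1)
        hits = 0
        n_outer = 25
        for k in range(n_outer):
            ts = sd.simulate_ssm(p, 100, seed=40_000 + k)
            fit = sd.fit_mle(ts, options=sd.FitOptions(compute_se=False))
            boot = sd.parametric_bootstrap(fit, 100, B=49, seed=50_000 + 100 * k)
            if boot.ci_low["sigma_eta"] <= 1.0 <= boot.ci_high["sigma_eta"]:
                hits += 1
        assert 0.8 <= hits / n_outer <= 1.0

    def test_low_signal_intervals_touch_boundary(self):
        p = sd.SSMParams(rho=0.7, sigma_eta=0.02, sigma_eps=0.1)
        ts = sd.simulate_ssm(p, 100, seed=61)
        fit = sd.fit_mle(ts, options=sd.FitOptions(compute_se=False))
        boot = sd.parametric_bootstrap(fit, 100, B=39, seed=62)
        # wide interval reaching (effectively) zero for at least one SD
        near_zero = (
            boot.ci_low["sigma_eta"] < 1e-3 or boot.ci_low["sigma_eps"] < 1e-3
        )
        assert near_zero

    def test_state_bands_returned_with_series(self, short_series):
        fit = sd.fit_mle(short_series, options=sd.FitOptions(compute_se=False))
        boot = sd.parametric_bootstrap(fit, short_series.n, B=5, seed=9,
                                       series=short_series)
        assert boot.state_ci_low.shape == short_series.y.shape
        assert np.all(boot.state_ci_low <= boot.state_ci_high + 1e-12)
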