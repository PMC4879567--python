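"""Simulate one AR(1)-plus-noise series and fit it by maximum likelihood.

The model:  x_t = rho x_{t-1} + eta_t (process),  y_t = x_t + eps_t
(observation).  We simulate at (sigma_eps, rho, sigma_eta) = (0.1, 0.7, 0.2)
with x0 = 0 known, fit all three parameters by maximizing the exact Kalman
marginal likelihood from three starts, and print estimates with 95% Wald
intervals.  Watch the boundary flags: a flagged SD means the likelihood
cannot distinguish the estimate from zero.
"""

import ssmdiag as sd

truth = sd.SSMParams(rho=0.7, sigma_eta=0.2, sigma_eps=0.1, x0=0.0)
series = sd.simulate_ssm(truth, n=100, seed=42)

fit = sd.fit_mle(series)
ci = sd.wald_ci(fit, level=0.95)

print(f"log-likelihood at the MLE: {fit.loglik_max:.3f}  (converged={fit.converged})")
print(f"{'parameter':>10} {'truth':>6} {'estimate':>9} {'95% CI':>22} boundary")
for name, tv in (("sigma_eps", 0.1), ("rho", 0.7), ("sigma_eta", 0.2)):
    lo, hi = ci[name]
    print(
        f"{name:>10} {tv:>6.2f} {fit.theta_hat[name]:>9.4f} "
        f"[{lo:>8.4f}, {hi:>8.4f}]  {fit.boundary_flags[name]}"
    )

out = sd.kalman_smooth(fit.params_hat, series)
rmse = sd.state_rmse(out.smoothed_mean, series.x_true)
print(f"\nsmoothed-state RMSE against the simulated truth: {rmse:.4f}")
print("(compare with the measurement SD 0.1: smaller means the filter is"
      " recovering signal the raw observations do not show)")
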