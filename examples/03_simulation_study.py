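"""A scaled-down replica of the estimability simulation study.

For each process SD in the grid we simulate 25 series (n = 100, rho = 0.7,
sigma_eps = 0.1), fit each twice — all parameters free, and with sigma_eps
fixed at its true value — and compare the smoothed-state RMSE under the
estimated parameters to the RMSE under the true parameters.  The headline
number is the percentage of replicates where estimation inflates the state
error by at least 50%.  The full-size study (200 replicates per scenario)
is run by scripts/acceptance.py.
"""

import ssmdiag as sd

config = sd.StudyConfig(n_replicates=25, base_seed=0, fit_free=True,
                        fit_fixed_eps=True)
study = sd.run_study(config)

free = sd.proportion_exceeding(study, factor=1.5, which_fit="free")
fixed = sd.proportion_exceeding(study, factor=1.5, which_fit="fixed_eps")
print(f"replicates: {len(study.replicates)}")
print(f"% with RMSE_hat >= 1.5 x RMSE_true, free fit:        {free:.1f}")
print(f"% with RMSE_hat >= 1.5 x RMSE_true, sigma_eps fixed: {fixed:.1f}")
print("(the first number is the cost of estimating all parameters;"
      " fixing the measurement error removes most of it)\n")

summary = sd.summarize_study(study)
cols = ["sigma_eta", "pct_exceeding", "sigma_eps_boundary_prop",
        "sigma_eps_bimodal", "rmse_hat_median", "rmse_true_median"]
print(summary[cols].to_string(index=False))
print("\nproblems concentrate where sigma_eps/sigma_eta is large (top rows):"
      " boundary estimates and bimodal estimate distributions appear, and"
      " the median RMSE under estimated parameters pulls away from the"
      " RMSE under the truth.")
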