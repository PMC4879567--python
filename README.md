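# ssmdiag

Estimability diagnostics for simple linear Gaussian state-space models.

State-space models (SSMs) are the standard tool in ecology for separating
biological variability from measurement error in time series — population
counts, animal movement paths, telemetry.  Even the simplest SSM, however,
can fail to deliver usable parameter estimates precisely in the regime it
was built for: when measurement error dominates process stochasticity, the
likelihood becomes flat or multimodal, variance estimates collapse to zero,
and the biased parameters contaminate the state estimates that downstream
ecological conclusions rest on.  `ssmdiag` reproduces this phenomenon end to
end — simulator, exact-likelihood fitter, diagnostics, the full simulation
study, and a 2-D animal-movement application — so that the failure modes
and their remedies can be studied quantitatively.

## The model

The core model is the univariate AR(1)-plus-noise SSM

```
x_t = ρ x_{t−1} + η_t,    η_t ~ N(0, σ_η²)     (process equation)
y_t = x_t + ε_t,          ε_t ~ N(0, σ_ε²)     (observation equation)
```

with x₀ known (or Gaussian).  θ = (σ_ε, ρ, σ_η) is estimated by maximizing
the exact marginal likelihood L(θ; y) computed by the Kalman
prediction-error decomposition; states are estimated by the RTS smoother,
x̂_t = E[x_t | y₁..y_n].  State recovery is scored by the root-mean-square
error RMSE = √(Σ_t (x̂_t − x_t)² / n) against the simulated truth, computed
once under the estimated parameters (RMSE_θ̂) and once under the true ones
(RMSE_θ).  Stationarity links the model to an ARMA(1,1) with φ = ρ; the
redundancy index |φ + θ_MA| → 0 as σ_ε/σ_η grows, which is why the
parameters become unidentifiable exactly when SSMs are most needed.

The 2-D application models daily animal displacement as voluntary movement
plus environmental drift observed with error (the drift-corrected series
z_t = y_t − s_t is an AR(1)-plus-noise model per coordinate), and derives
the total voluntary displacement d = Σ_t ‖ĉ_t‖ over a standardized 342 days
as an energy-expenditure proxy.

## Worked example

```python
import ssmdiag as sd

truth = sd.SSMParams(rho=0.7, sigma_eta=0.2, sigma_eps=0.1, x0=0.0)
series = sd.simulate_ssm(truth, n=100, seed=42)
fit = sd.fit_mle(series)          # multi-start exact-likelihood MLE
print(fit.theta_hat)
out = sd.kalman_smooth(fit.params_hat, series)
print(sd.state_rmse(out.smoothed_mean, series.x_true))
```

prints

```
{'sigma_eps': 0.0957..., 'rho': 0.6878..., 'sigma_eta': 0.1619...}
0.0808...
```

— the estimates sit near the truth (0.1, 0.7, 0.2) and the smoothed states
recover the latent path with error 0.08, below the 0.1 measurement SD.
This is the benign regime; rerun with `sigma_eta=0.01` and the fit lands on
a boundary (σ̂ near zero) with a flat profile likelihood — see
`examples/02_profile_likelihood.py`.

The `examples/` directory walks through each capability: single fits with
Wald intervals (`01`), profile-likelihood pathology and the known-states
diagnostic (`02`), the scaled-down simulation study (`03`), ARMA redundancy
(`04`), the synthetic bear study with the inflated energy proxy and the
pooled-measurement-error remedy (`05`), and parametric-bootstrap intervals
(`06`).  Each script prints its numbers with a line on what they mean.

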