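"""Why the estimation fails: ARMA(1,1) parameter redundancy.

The stationary AR(1)-plus-noise model is observationally an ARMA(1,1) with
AR root phi = rho.  As the measurement-error-to-process ratio grows, the MA
root approaches -phi and the roots cancel: the model becomes observationally
indistinguishable from white noise, so no amount of data identifies the
parameters.  The redundancy index |phi + theta| quantifies the distance from
exact cancellation.
"""

import ssmdiag as sd

print(f"{'sigma_eps/sigma_eta':>19} {'phi':>6} {'theta_MA':>9} "
      f"{'sigma_e':>8} {'|phi+theta|':>12}")
for ratio in (0.1, 0.5, 1.0, 2.0, 5.0, 10.0):
    p = sd.SSMParams(rho=0.7, sigma_eta=1.0, sigma_eps=ratio)
    a = sd.ssm_to_arma(p)
    print(f"{ratio:>19.1f} {a.phi:>6.2f} {a.theta_ma:>9.4f} "
          f"{a.sigma_e:>8.4f} {sd.redundancy_index(p):>12.4f}")

print("\nAt ratio 10 the index is near zero: the AR and MA roots cancel and")
print("(rho, sigma_eta, sigma_eps) are redundant — exactly the regime where")
print("the simulation study shows boundary estimates and inflated state error.")
print("At ratio 0.1 the MA term vanishes instead: the model behaves as a")
print("pure AR(1) and the measurement error is simply ignored.")
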