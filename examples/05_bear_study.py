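"""Synthetic polar-bear drift-correction study.

Fifteen bears x 342 days of 2-D daily displacements: observed bear
displacement y_t = voluntary movement c_t + ice drift g_t (GPS error
negligible), observed drift s_t = g_t + error.  Subtracting gives the
drift-corrected series z_t = c_t - error, fitted per coordinate as an
AR(1)-plus-noise model with c_0 ~ N(0, 15^2) km.  The energy-expenditure
proxy is the total voluntary displacement d over 342 days.

Bears whose estimated ice-error SD (sigma_h) collapses to the boundary have
smoothed movements glued to the noisy observations, which inflates d — the
biological-inference distortion this package exists to demonstrate.
"""

import numpy as np

import ssmdiag as sd

bears = sd.simulate_bear_paths(sd.BearSimConfig(seed=7))
fits = [sd.fit_bear(b, options=sd.FitOptions(compute_se=False)) for b in bears]

print(f"{'bear':>7} {'sigma_h (u,v)':>16} {'sigma_q (u,v)':>16} "
      f"{'d (km)':>8} boundary")
for f in sorted(fits, key=lambda f: f.d):
    sh = f.sigma_h
    sq = f.sigma_q
    print(f"{f.bear_id:>7} ({sh['u']:>6.2f},{sh['v']:>6.2f}) "
          f"({sq['u']:>6.2f},{sq['v']:>6.2f}) {f.d:>8.0f} "
          f"{'  <-- ' if f.boundary_sigma_h else ''}"
          f"{'sigma_h at boundary' if f.boundary_sigma_h else ''}")

ds = np.array([f.d for f in fits])
bnd = np.array([f.boundary_sigma_h for f in fits])
print(f"\ntruth: sigma_h = 6 km/day, sigma_q = 12 km/day, rho = 0.6 per coordinate")
print(f"boundary bears: {bnd.sum()} of {len(fits)}")
if bnd.any() and (~bnd).any():
    print(f"median d, boundary bears:     {np.median(ds[bnd]):.0f} km")
    print(f"median d, non-boundary bears: {np.median(ds[~bnd]):.0f} km")
    print("the boundary bears sit at the top of the energy ranking not"
          " because they moved more, but because their fits mistake ice-data"
          " noise for voluntary movement")

pooled = sd.fit_pooled(bears)
print(f"\npooled fit (one sigma_h shared across bears):"
      f" sigma_h_u = {pooled.sigma_h['u']:.2f},"
      f" sigma_h_v = {pooled.sigma_h['v']:.2f} km/day")
print("pooling the measurement error across individuals is the structural"
      " remedy: more data per parameter, no per-bear boundary collapse")
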