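"""Recover the areal uptake capacity sigma*Vmax from noisy surface oxygen.

Generates a synthetic cell-surface oxygen profile from the stagnant-column
model (5 % Gaussian noise, 50 sample points, fixed seed), then inverts the
flux balance by least squares to estimate sigma*Vmax with a standard error.
"""

import zonesim as zs

truth = 3e-8  # mol m^-2 s^-1
case = zs.stagnant_mm_case(c0=0.21, depth=5e-3, diffusivity=3e-9,
                           sigma_vmax=truth, km=5e-3)
signal = case.analytic["surface_conc"]
profile = zs.synthetic_profile(case, noise_sd=0.05 * signal, n_points=50, seed=7)
est = zs.recover_vmax(profile, c0=0.21, depth=5e-3, diffusivity=3e-9, km=5e-3)

print(f"true sigma*Vmax      : {truth:.3e} mol m^-2 s^-1")
print(f"estimated            : {est.estimate:.3e} +/- {est.stderr:.1e}")
print(f"relative error       : {abs(est.estimate - truth) / truth * 100:.2f} %")
print(f"fitted surface O2    : {est.surface_conc:.4f} mol/m^3")
print()
print("With 5 % measurement noise over 50 points the uptake capacity is")
print("recovered to a few percent; the standard error follows from the")
print("spread of the profile by the delta method.")
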