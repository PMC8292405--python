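"""Global kinetic analysis of a flash-photolysis surface.

Simulates a three-intermediate (K -> M -> O -> ground) photocycle as a
difference-absorbance surface over 380-700 nm and 0.01-1000 ms with 5%
noise, then globally fits the irreversible sequential model and reports
the recovered decay time constants and the tabulated decay rates.
"""

import photocyclekit as pk

gt = pk.PhotocycleGroundTruth(decay_taus=(0.015, 6.4, 30.0), noise_sigma=0.05, seed=0)
surface = pk.generate_transient_surface(gt)
print(f"surface: {surface.delta_A.shape[0]} wavelengths x {surface.delta_A.shape[1]} times")

fit = pk.assign_intermediates(pk.fit_global_sequential(surface, n_intermediates=3))
rates = pk.rate_report(fit.model)

for label, tau, err, rate in zip(
    fit.model.labels, fit.model.decay_taus, fit.tau_stderr, rates.decay_rates
):
    print(f"{label}-decay: tau = {tau:8.4f} +- {err:.4f} ms   rate = {rate:.2f} ms^-1")
print(f"residual rms = {fit.residual_rms:.4f} dA (noise level was ~0.05 x peak)")

# Each tau is the lifetime of one photocycle intermediate; its reciprocal,
# rounded to two decimals, is the decay rate as listed in comparative tables
# of microbial rhodopsins (true values here: 0.015, 6.4 and 30 ms).
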