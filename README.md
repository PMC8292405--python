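# photocyclekit

Kinetic and spectroscopic analysis for microbial-rhodopsin photochemistry,
aimed at the standard characterization workflow for a light-driven proton
pump: flash-photolysis photocycle kinetics, acid-titration pKa analysis,
retinal-isomer HPLC quantification, and proton-flux assays (pyranine
transients and illuminated cell-suspension pH traces). Every measurement has
a matched synthetic-data generator, so each fitting stage can be validated
end-to-end by parameter recovery from known ground truth — no instrument
data required.

## The models

**Photocycle.** After photoexcitation the pigment traverses an irreversible
sequential chain K → M → O → ground, with first-order decays
τ_K, τ_M, τ_O. The occupancies c_i(t) follow the Bateman closed form for a
linear chain, and the measured difference-absorbance surface is bilinear in
occupancies and species-associated difference spectra (SADS):

    ΔA(λ, t) = Σ_i c_i(t) · SADS_i(λ)

`fit_global_sequential` estimates the τ's by nonlinear least squares with
the SADS eliminated analytically at every step (variable projection), labels
the components K/M/O from their spectral bands (red-positive early → K,
blue-positive → M, red-positive late → O), and reports decay rates 1/τ
rounded half-even to two decimals, the convention of comparative tables.

**Titration.** Acidification protonates the Schiff-base counterion(s),
shifting the visible band. The difference absorbance at a wavelength w obeys
a double Henderson–Hasselbalch curve

    ΔA_w(pH) = b_w + a1_w / (1 + 10^(pH − pKa1)) + a2_w / (1 + 10^(pH − pKa2))

with the two pKa's shared across wavelengths. The package also locates λmax
by 3-point parabolic interpolation, scores isosbestic points (their absence
flags ≥ 3 spectral states), and estimates sample purity from A280/Avis.

**HPLC.** Retinal oximes elute as separate 15-syn/15-anti peaks per isomer
(Ts/Ta for all-trans). Peaks are integrated above local linear baselines,
converted to molar amounts with per-oxime ε(360 nm), and pooled per isomer.

**Proton flux.** The pyranine ΔA450 transient is a negative-going
biexponential, −A·(e^(−t/τ_uptake) − e^(−t/τ_release)) (normalised to dip
depth A); release/uptake time constants are compared with the M-decay
(O-formation) and O-decay constants. Suspension pH traces are scored
against a linearly extrapolated pre-light baseline, with CCCP and
empty-vector controls deciding the pump verdict.

## Worked example

```python
import photocyclekit as pk

gt = pk.PhotocycleGroundTruth(decay_taus=(0.015, 6.4, 30.0), noise_sigma=0.05, seed=0)
surface = pk.generate_transient_surface(gt)          # 65 wavelengths x 200 times
fit = pk.assign_intermediates(pk.fit_global_sequential(surface))
rates = pk.rate_report(fit.model)
for label, tau, rate in zip(fit.model.labels, fit.model.decay_taus, rates.decay_rates):
    print(f"{label}-decay: tau = {tau:8.4f} ms   rate = {rate:.2f} ms^-1")
```

prints

```
K-decay: tau =   0.0147 ms   rate = 68.26 ms^-1
M-decay: tau =   6.5545 ms   rate = 0.15 ms^-1
O-decay: tau =  29.2128 ms   rate = 0.03 ms^-1
```

i.e. from a surface carrying 5% noise the global fit recovers the true
lifetimes (0.015, 6.4, 30 ms) to within a few percent; the reciprocals,
rounded to two decimals, are the M- and O-decay rates as they would appear
in a comparative table. The `examples/` directory has one narrative script
per capability (`photocycle_fit.py`, `titration_pka.py`,
`hplc_composition.py`, `proton_flux.py`, `full_pipeline.py`); each builds a
small synthetic input, runs the analysis and explains the printed numbers.

A thin CLI mirrors the library:

```
photocyclekit simulate surface --seed 0 --out out/
photocyclekit fit-photocycle --surface out/transient_surface.csv --out out/
photocyclekit run --config demo.yaml
```

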