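# Methods

This note records the models, numerical choices and known limitations behind
photocyclekit, in the package's own words. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Sequential photocycle model

The photocycle is a linear chain of irreversible first-order decays,
P1 → P2 → … → Pn → ground (canonically K → M → O → ground), with one
lifetime τ_i (ms) per intermediate. With initial occupancy
`excited_fraction` in the first intermediate, the occupancies follow the
Bateman closed form

    c_i(t) = f · (Π_{j<i} k_j) · Σ_{j≤i} e^(−k_j t) / Π_{l≤i, l≠j} (k_l − k_j),

k_i = 1/τ_i. The recovered-ground population is defined as
f − Σ_i c_i(t), so conservation holds to machine precision by construction;
the substantive check is that the closed form agrees with the exact matrix
exponential of the chain's rate matrix (tested to 1e-8 absolute over four
decades of random lifetimes).

**Degeneracy.** The Bateman denominators have removable singularities at
equal rates. Rates closer than 1e-9 (relative to the largest) are perturbed
by 1e-6 relative, with a logged warning, instead of implementing the
confluent limit. Consequence: occupancies near exact degeneracy are accurate
only to roughly the perturbation scale (~1e-10 in occupancy units), which is
why the monotonicity property tests exclude nearly degenerate chains.

## Global fitting (variable projection)

`fit_global_sequential` optimises only the lifetimes, in log space
(positivity by construction, and the photocycle spans > 3 decades). At
every iteration the SADS matrix is obtained by linear least squares from
the current occupancy basis; a rank-deficient solve (more intermediates than
the data support) is a hard error. The nonlinear solver is
`scipy.optimize.least_squares` (trust-region reflective, Jacobian-based
`x_scale`). Defaults:

- initialisation: log-equispaced lifetimes across the interior of the time
  grid (deterministic; no random restarts);
- fitted lifetimes sorted ascending, labels (K, M, O) applied in that order
  for three-component fits;
- uncertainties from the Jacobian covariance of the projected
  (lifetime-only) problem, scaled by residual variance. This ignores the
  SADS–lifetime covariance cross-terms, so the stderr is an approximation
  in the usual variable-projection sense.

The fit uses the full wavelength grid by default; `wavelengths=(400, 540,
600)` restricts it to the classical three-trace procedure, which the global
fit contains as a special case.

**Intermediate assignment** is evidence-based, not positional: a component
is red-positive if its SADS maximum above 570 nm exceeds 10% of the global
|SADS| maximum, blue-positive analogously below 430 nm. Earliest
red-positive → K, blue-dominant → M, latest red-positive → O; anything
matching no window is labelled `unassigned`, and orderings other than
(K, M, O) are flagged non-canonical rather than silently relabelled.

**Rate reporting** is 1/τ exactly, rounded half-even at two decimals —
the convention of comparative tables of M- and O-decay rates.

## Double-pKa titration fit

The fitted quantity is difference absorbance versus pH (relative to the
spectrum at the reference pH), modelled as two base-10 logistic terms with
per-wavelength amplitudes/baselines and globally shared pKa's, solved by
variable projection like the photocycle fit. Numerical choices:

- both pKa's are constrained to [min(pH) − 1, max(pH) + 1]. A pKa far
  outside the sampled range makes its logistic column effectively constant
  and exactly collinear with the baseline column; unbounded fits can drift
  into that degenerate valley on noisy data.
- a deterministic multi-start (five fixed initialisations spread over the
  pH range) guards against the local minimum where one transition saturates
  against the range boundary; the lowest-cost solution wins.
- output is always ordered pKa1 > pKa2; fits with |pKa1 − pKa2| < 0.05 or a
  transition amplitude below 2% of the amplitude scale are flagged
  degenerate; a pKa within one unit of the range edge triggers a warning
  and an honestly inflated stderr.

λmax uses 3-point parabolic interpolation through the maximal sample
(0.1 nm reporting resolution; edge maxima are returned as the edge with a
warning, never extrapolated). The isosbestic score at λ is
max_pH |ΔA(λ)| normalised by the global max |ΔA|; a crossing is declared
below 0.02. The threshold tolerates generator noise at default σ while
rejecting the three-state configuration, and the score is scale-invariant.

Purity is 100 · (A_vis · ε280/ε_vis)/A280 with ε_vis defaulting to the
generic microbial-rhodopsin 50,000 M⁻¹cm⁻¹; ε280 is sequence-specific and
must be supplied. Values above 100% are clipped with a warning since they
indicate a mis-set ε.

## HPLC quantification

Peaks are integrated trapezoidally above a per-window linear baseline. The
baseline line is least-squares fitted to the outer 10% of the window at
each end (fallback: the two endpoint samples when a window is too narrow).
Fitting the fringes rather than connecting two raw endpoint samples keeps
the baseline unbiased under i.i.d. noise — a two-sample baseline tilts by
O(σ) × window and visibly biases minor-isomer fractions. Windows with
negative net area are zeroed with a warning (areas below 1e-12 are treated
as numerical zeros). 15-syn and 15-anti oxime areas of the same isomer are
always pooled; ε correction is per-oxime and a missing ε is a hard error —
`equal_epsilon_table` exists for the case where true coefficients are
unavailable, and warns loudly that composition is then area-weighted.
Percentages are reported rounded to integers.

## Proton flux

The pyranine model is ΔA450(t) = −A·(e^(−t/τu) − e^(−t/τr))/norm + offset,
normalised so A is the dip depth; its minimum lies at
t* = ln(τu/τr)/(1/τr − 1/τu). Traces must be biphasic and negative-going
(release = acidification = ΔA450 < 0); sign-flipped or monotone traces are
rejected rather than refitted, because the sign carries the transport
direction. Raw traces without background subtraction are refused
(`has_pyranine=False`).

Consistency with the photocycle compares τ_release with the M-decay
lifetime (which forms O) and τ_uptake with the O-decay lifetime; both
ratios are always reported and "consistent" means both lie within a factor
of 5. The factor is a package convention: the comparison is
order-of-magnitude, and a release/O-formation ratio near 0.23 should count
as consistent.

Pump-assay amplitude is the gap between the linearly extrapolated pre-light
baseline (≥ 30 s required) and the minimum pH during illumination, with the
minimum taken on a boxcar-smoothed trace (window ≈ 5% of the light period).
The raw per-sample minimum is a max-of-noise statistic that sits near
+2.7σ even for pump-free traces and would make the CCCP/empty-vector
controls flaky. A pump verdict requires amplitude > 3 × the baseline-residual
s.d. and, when a CCCP trace of the same construct is present, a CCCP
amplitude below 20% of the untreated one. Both thresholds are package
conventions for a qualitative observation.

## Synthetic-data generators

Each generator is a pure function of (ground truth, grids, seed); noiseless
output satisfies the consuming module's forward model to 1e-12, and noise
is additive i.i.d. Gaussian. `noise_sigma` is a fraction of the noiseless
peak |signal| for the spectroscopic generators, and absolute pH units for
the pump assay (so pump-free control traces still carry noise). Defaults,
chosen once as realistic study conditions:

- **Photocycle**: τ = (0.015, 6.4, 30) ms; SADS as sums of Gaussians in
  wavelength with positive bands near 600 nm (K), 400 nm (M), 600 nm (O)
  and a shared −1.0 bleach at 540 nm (σ 35 nm); grids 380–700 nm at 5 nm
  and log-spaced 0.01–1000 ms (200 points); noise 5% of peak,
  representative of averaged flash-photolysis data.
- **Titration**: pKa (3.0, 1.5); end-member bands at 533/549/548 nm with
  amplitudes (1.00, 1.02, 0.90) and σ (37, 49, 49) nm, placed so the
  acid-minus-neutral difference spectrum has its extrema near 591 and
  516 nm and so the three states are genuinely distinct (no isosbestic
  point); 12 pH points from 7.1 to 0.98; wavelength grid 380–700 nm at
  1 nm; noise 2% of peak absorbance. The protonation-state weights are
  two independent-site logistics, (1−p1, p1−p2, p2).
- **Chromatogram**: dark-adapted 95:5 all-trans:13-cis, 40% of each isomer
  in the 15-syn peak; retention times 8.7/10.5/12.3/14.0 min, peak σ
  0.15 min; equal ε (52,000) by default; 0–20 min at 0.002 min (10 Hz
  detector); noise 1% of the tallest peak; integration windows at ±5σ.
- **Pump assay**: baseline pH 6.5 (assay range 6.4–6.6), light window
  120–300 s (3 min) inside a 600 s trace, single-exponential approach to
  the light-on plateau with τ_on = 30 s and the same constant for
  post-illumination recovery (the trace shape is not otherwise
  constrained), amplitude 0.08 pH, drift −2e-5 pH/s, noise 0.002 pH.
- **Pyranine**: τ = (1.5, 47) ms, dip depth 0.01 ΔA, log-spaced
  0.1–1000 ms grid (300 points), noise 5% of dip depth (traces are
  1000-shot averages).

What the generators do *not* emulate: shot-noise/heteroscedastic detector
statistics, laser-pulse convolution (instrument response), temperature
dependence, chromatographic tailing or retention drift, electrode response
lag. Passing recovery tests therefore demonstrates correctness of the
estimators under idealised Gaussian-noise conditions, not robustness to
every instrumental artefact of real data.

## Problem sizes

Test-suite and acceptance computations run on the default grids above
(65×200 surface, 12-point titration, 10,001-point chromatogram, 300-point
pyranine trace, 601-point pump traces); Monte-Carlo style checks use tens
of seeds. These sizes match the desk scale of the emulated experiments.

## Pipeline and I/O

`run_pipeline` executes stages in a fixed dependency order (the pyranine
stage consumes the photocycle fit for its consistency check), derives one
independent sub-seed per stage from the master seed via
`numpy.random.SeedSequence`, and embeds the config hash, seeds and package
version in the report; identical configs reproduce every artifact
bit-for-bit. All tabular interchange is UTF-8 CSV with unit-suffixed
columns written at 17 significant digits (lossless float round-trip);
configs and results are YAML/JSON. Validation (exactly one of
simulate/analyze per stage, existing paths, ε table present for HPLC
analysis) happens before any computation.

## Known limitations

- The sequential model is strictly irreversible and unbranched; reversible
  or parallel schemes, and spectrotemporal lifetime-density analysis, are
  out of scope.
- SADS uncertainties are not reported (only lifetime stderr).
- The two-pKa spectral decomposition assumes independent protonation sites;
  strongly coupled sites would need a thermodynamic partition-function
  model.
- Absolute ΔA scales are arbitrary (the photoexcited fraction is not
  identifiable from a single surface), so SADS amplitudes are relative.
- The 549 → 548 nm shift of the third titration end-member is within
  plausible measurement precision; the generator treats the third state as
  configurable and no analysis asserts its distinguishability from the
  second by peak position alone (the default makes it distinct mainly by
  amplitude).
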