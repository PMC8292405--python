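"""Synthetic-data generators for every measurement the pipeline analyses.

Each generator is a pure function of (ground truth, grids, seed): identical
inputs give bit-identical outputs, and with ``noise_sigma = 0`` the output
satisfies the exact forward model of the consuming analysis module.  That
makes every fitting stage verifiable by parameter recovery without any
instrument data.

Noise is additive i.i.d. Gaussian.  For the spectroscopic generators
``noise_sigma`` is expressed as a fraction of the peak |signal| of the
noiseless trace; for the pump assay it is in absolute pH units (so that
no-pump control traces still carry realistic noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import (
    Chromatogram,
    PeakWindow,
    ProtonFluxTrace,
    PumpAssayTrace,
    TitrationSeries,
    TransientSurface,
)
from .kinetics import SequentialModel, compose_surface, sequential_occupancies

GAUSS_NORM = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band: centre (nm), amplitude (ΔA or A), sigma (nm)."""

    center: float
    amplitude: float
    sigma: float

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((wavelengths - self.center) / self.sigma) ** 2)


def _sum_bands(bands, wavelengths: np.ndarray) -> np.ndarray:
    out = np.zeros_like(wavelengths, dtype=float)
    for b in bands:
        out += b(wavelengths)
    return out


# ---------------------------------------------------------------------------
# photocycle transient surface
# ---------------------------------------------------------------------------

def _default_sads_templates() -> dict[str, tuple[GaussianBand, ...]]:
    """Canonical difference-spectrum shapes for a K/M/O photocycle.

    Every intermediate shares the negative ground-state bleach near 540 nm;
    K and O carry red-shifted positive bands near 600 nm, M the blue-shifted
    band near 400 nm of the deprotonated Schiff base.
    """
    bleach = GaussianBand(540.0, -1.0, 35.0)
    return {
        "K": (GaussianBand(600.0, 0.6, 40.0), bleach),
        "M": (GaussianBand(400.0, 0.8, 30.0), bleach),
        "O": (GaussianBand(600.0, 0.9, 45.0), bleach),
    }


@dataclass
class PhotocycleGroundTruth:
    """True parameters behind a simulated flash-photolysis surface."""

    intermediate_labels: tuple[str, ...] = ("K", "M", "O")
    decay_taus: tuple[float, ...] = (0.015, 6.4, 30.0)  # ms
    sads_templates: dict[str, tuple[GaussianBand, ...]] = field(
        default_factory=_default_sads_templates
    )
    excited_fraction: float = 1.0
    noise_sigma: float = 0.05  # fraction of peak |dA|
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.intermediate_labels)) != len(self.intermediate_labels):
            raise ValueError("intermediate labels must be unique")
        if len(self.decay_taus) != len(self.intermediate_labels):
            raise ValueError("one decay tau per intermediate required")
        if any(t <= 0 for t in self.decay_taus):
            raise ValueError("decay taus must be > 0")
        if not 0 < self.excited_fraction <= 1:
            raise ValueError("excited_fraction must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        missing = [l for l in self.intermediate_labels if l not in self.sads_templates]
        if missing:
            raise ValueError(f"sads_templates missing intermediates: {missing}")

    def sads_matrix(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.array(
            [_sum_bands(self.sads_templates[l], wavelengths) for l in self.intermediate_labels]
        )


def default_wavelength_grid() -> np.ndarray:
    """380-700 nm at 5 nm intervals (flash-photolysis convention)."""
    return np.arange(380.0, 700.0 + 2.5, 5.0)


def default_time_grid() -> np.ndarray:
    """Log-spaced 0.01-1000 ms, 200 points (photocycle spans ~5 decades)."""
    return np.geomspace(0.01, 1000.0, 200)


def generate_transient_surface(
    gt: PhotocycleGroundTruth,
    wavelength_grid=None,
    time_grid=None,
) -> TransientSurface:
    """Simulate ΔA(λ, t) from the irreversible sequential chain.

    ΔA(λ, t) = Σ_i c_i(t) · SADS_i(λ) + Gaussian noise.
    """
    wl = default_wavelength_grid() if wavelength_grid is None else np.asarray(
        wavelength_grid, dtype=float
    )
    t = default_time_grid() if time_grid is None else np.asarray(time_grid, dtype=float)
    if wl.size == 0 or t.size == 0:
        raise ValueError("grids must be non-empty")
    model = SequentialModel(np.asarray(gt.decay_taus), labels=gt.intermediate_labels)
    occ, _ = sequential_occupancies(model, t, gt.excited_fraction)
    sads = gt.sads_matrix(wl)
    surface = compose_surface(occ, sads, wl, t, meta={"source": "synthetic"})
    if gt.noise_sigma > 0:
        rng = np.random.default_rng(gt.seed)
        scale = gt.noise_sigma * float(np.max(np.abs(surface.delta_A)))
        surface.delta_A = surface.delta_A + rng.normal(0.0, scale, surface.delta_A.shape)
    return surface


# ---------------------------------------------------------------------------
# acid titration series
# ---------------------------------------------------------------------------

DEFAULT_TITRATION_PH = (7.1, 5.0, 4.0, 3.5, 3.0, 2.6, 2.2, 1.9, 1.7, 1.4, 1.2, 0.98)


@dataclass
class TitrationGroundTruth:
    """True parameters behind a simulated acid-titration series.

    The three protonation states (counterion deprotonated; primary
    counterion protonated; both counterions protonated) are Gaussian bands
    whose default centres reproduce the 533 -> 549 -> 548 nm shift sequence.
    """

    pka_values: tuple[float, float] = (3.0, 1.5)
    state_lambda_max: tuple[float, float, float] = (533.0, 549.0, 548.0)
    state_bandwidths: tuple[float, float, float] = (37.0, 49.0, 49.0)  # Gaussian sigma, nm
    state_amplitudes: tuple[float, float, float] = (1.0, 1.02, 0.90)
    pH_list: tuple[float, ...] = DEFAULT_TITRATION_PH
    reference_pH: float = 7.1
    noise_sigma: float = 0.02  # fraction of peak absorbance
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pka_values) != 2:
            raise ValueError("exactly two pKa values required")
        pk = sorted(self.pka_values, reverse=True)
        if abs(pk[0] - pk[1]) < 1e-6:
            raise ValueError("pKa values equal within 1e-6: protonation states ambiguous")
        object.__setattr__(self, "pka_values", (pk[0], pk[1]))
        if any(p < 0 or p > 14 for p in self.pH_list):
            raise ValueError("all pH values must lie in [0, 14]")
        if not any(abs(p - self.reference_pH) < 1e-12 for p in self.pH_list):
            raise ValueError("reference_pH must be present in pH_list")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def state_spectra(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.array(
            [
                GaussianBand(c, a, s)(wavelengths)
                for c, a, s in zip(
                    self.state_lambda_max, self.state_amplitudes, self.state_bandwidths
                )
            ]
        )


def protonation_state_weights(pH, pka1: float, pka2: float) -> np.ndarray:
    """Occupancies of the three protonation states at given pH.

    Two independent-site Henderson-Hasselbalch transitions with
    pKa1 > pKa2: p_i = 1 / (1 + 10^(pH - pKa_i)) is the protonated fraction
    of site i.  Weights (1 - p1, p1 - p2, p2) are non-negative and sum to 1.
    Shape: (3, n_pH).
    """
    pH = np.atleast_1d(np.asarray(pH, dtype=float))
    p1 = 1.0 / (1.0 + 10.0 ** (pH - pka1))
    p2 = 1.0 / (1.0 + 10.0 ** (pH - pka2))
    return np.array([1.0 - p1, p1 - p2, p2])


def titration_wavelength_grid() -> np.ndarray:
    """380-700 nm at 1 nm steps (static spectrophotometer resolution)."""
    return np.arange(380.0, 700.0 + 0.5, 1.0)


def generate_titration_series(
    gt: TitrationGroundTruth,
    wavelength_grid=None,
) -> TitrationSeries:
    """Simulate absorption spectra across the acid titration.

    Each spectrum is the mixture of the three end-member spectra weighted by
    the two-site protonation fractions at that pH, plus noise.
    """
    wl = titration_wavelength_grid() if wavelength_grid is None else np.asarray(
        wavelength_grid, dtype=float
    )
    pH = np.asarray(gt.pH_list, dtype=float)
    if pH.size == 0:
        raise ValueError("pH_list must be non-empty")
    weights = protonation_state_weights(pH, *gt.pka_values)  # (3, n_pH)
    states = gt.state_spectra(wl)  # (3, n_wl)
    spectra = weights.T @ states
    if gt.noise_sigma > 0:
        rng = np.random.default_rng(gt.seed)
        scale = gt.noise_sigma * float(np.max(np.abs(spectra)))
        spectra = spectra + rng.normal(0.0, scale, spectra.shape)
    return TitrationSeries(
        pH_values=pH, wavelengths=wl, spectra=spectra, reference_pH=gt.reference_pH
    )


# ---------------------------------------------------------------------------
# retinal-oxime chromatogram
# ---------------------------------------------------------------------------

@dataclass
class ChromatogramGroundTruth:
    """True composition behind a simulated retinal-oxime chromatogram.

    Each retinal isomer is derivatised into 15-syn and 15-anti oximes that
    elute as separate peaks (Ts/Ta for all-trans); quantification must pool
    them.  Defaults are a dark-adapted 95:5 all-trans / 13-cis mixture.
    """

    isomer_fractions: dict[str, float] = field(
        default_factory=lambda: {"all-trans": 0.95, "13-cis": 0.05}
    )
    syn_anti_split: dict[str, float] = field(
        default_factory=lambda: {"all-trans": 0.40, "13-cis": 0.40}
    )
    retention_times: dict[str, float] = field(
        default_factory=lambda: {"13s": 8.7, "Ts": 10.5, "13a": 12.3, "Ta": 14.0}
    )
    oxime_map: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "Ts": ("all-trans", "syn"),
            "Ta": ("all-trans", "anti"),
            "13s": ("13-cis", "syn"),
            "13a": ("13-cis", "anti"),
        }
    )
    peak_widths: dict[str, float] = field(
        default_factory=lambda: {"Ts": 0.15, "Ta": 0.15, "13s": 0.15, "13a": 0.15}
    )
    extinction_table: dict[str, float] = field(
        default_factory=lambda: {"Ts": 52000.0, "Ta": 52000.0, "13s": 52000.0, "13a": 52000.0}
    )
    amount_scale: float = 1e-5  # arbitrary molar scale -> O(0.1) absorbance peaks
    baseline: float = 0.005
    noise_sigma: float = 0.01  # fraction of tallest peak
    adaptation_state: str = "dark"
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.isomer_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"isomer fractions must sum to 1 (got {total})")
        if any(f < 0 or f > 1 for f in self.isomer_fractions.values()):
            raise ValueError("isomer fractions must lie in [0, 1]")
        if any(e <= 0 for e in self.extinction_table.values()):
            raise ValueError("extinction coefficients must be > 0")
        rts = list(self.retention_times.values())
        if len(set(rts)) != len(rts):
            raise ValueError("retention times must be distinct")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def peak_amounts(self) -> dict[str, float]:
        """Molar amount (arbitrary units) eluting in each oxime peak."""
        amounts = {}
        for label, (isomer, form) in self.oxime_map.items():
            frac = self.isomer_fractions.get(isomer, 0.0)
            split = self.syn_anti_split.get(isomer, 0.5)
            amounts[label] = frac * (split if form == "syn" else 1.0 - split)
        return amounts


def default_rt_grid() -> np.ndarray:
    """0-20 min at 0.002 min steps (10 Hz UV detector sampling)."""
    return np.arange(0.0, 20.0 + 0.001, 0.002)


def generate_chromatogram(
    gt: ChromatogramGroundTruth,
    rt_grid=None,
) -> Chromatogram:
    """Simulate an A360 chromatogram as a sum of Gaussian oxime peaks.

    Peak area is amount x epsilon x scale; integration windows at +-5 sigma
    around each retention time are attached to the output.
    """
    rt = default_rt_grid() if rt_grid is None else np.asarray(rt_grid, dtype=float)
    for label, centre in gt.retention_times.items():
        w = gt.peak_widths[label]
        if centre - 3 * w < rt[0] or centre + 3 * w > rt[-1]:
            raise ValueError(f"rt_grid does not cover peak {label} +- 3 widths")
    labels = sorted(gt.retention_times, key=gt.retention_times.get)
    for a, b in zip(labels, labels[1:]):
        gap = gt.retention_times[b] - gt.retention_times[a]
        if gap < max(gt.peak_widths[a], gt.peak_widths[b]):
            warnings.warn(
                f"peaks {a} and {b} closer than one width: integration unreliable",
                RuntimeWarning,
            )
    amounts = gt.peak_amounts()
    a360 = np.full_like(rt, gt.baseline)
    windows = []
    for label in labels:
        area = amounts[label] * gt.extinction_table[label] * gt.amount_scale
        sigma = gt.peak_widths[label]
        centre = gt.retention_times[label]
        a360 += (area / (sigma * GAUSS_NORM)) * np.exp(-0.5 * ((rt - centre) / sigma) ** 2)
        isomer, _ = gt.oxime_map[label]
        windows.append(PeakWindow(label, isomer, centre - 5 * sigma, centre + 5 * sigma))
    if gt.noise_sigma > 0:
        rng = np.random.default_rng(gt.seed)
        scale = gt.noise_sigma * float(np.max(a360 - gt.baseline))
        a360 = a360 + rng.normal(0.0, scale, a360.shape)
    return Chromatogram(
        retention_times=rt,
        a360=a360,
        adaptation_state=gt.adaptation_state,
        peak_windows=windows,
    )


# ---------------------------------------------------------------------------
# E. coli suspension pump assay
# ---------------------------------------------------------------------------

@dataclass
class PumpAssayGroundTruth:
    """True parameters behind a simulated light-induced pH trace.

    The light-on response approaches steady state as a single exponential
    (tau_on); after light-off the deviation relaxes back with the same
    time constant.  ``cccp=True`` or ``pump_amplitude=0`` abolish the signal.
    """

    baseline_pH: float = 6.5  # initial pH, within the 6.4-6.6 assay range
    pump_amplitude: float = 0.08  # maximal light-induced pH drop
    cccp: bool = False
    construct: str = "omr2"
    illumination_window: tuple[float, float] = (120.0, 300.0)  # s, 3 min on
    tau_on: float = 30.0  # s
    drift_rate: float = -2e-5  # pH/s, slow electrode drift
    noise_sigma: float = 0.002  # absolute pH units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        t_on, t_off = self.illumination_window
        if not t_off > t_on >= 0:
            raise ValueError("illumination window must be ordered and non-negative")
        if self.pump_amplitude < 0:
            raise ValueError("pump_amplitude must be >= 0")


def default_pump_time_grid() -> np.ndarray:
    return np.arange(0.0, 600.0 + 0.5, 1.0)


def generate_pump_assay(
    gt: PumpAssayGroundTruth,
    time_grid=None,
) -> PumpAssayTrace:
    """Simulate the suspension pH under an illumination window."""
    t = default_pump_time_grid() if time_grid is None else np.asarray(time_grid, dtype=float)
    t_on, t_off = gt.illumination_window
    if not (t[0] <= t_on and t_off <= t[-1]):
        raise ValueError("illumination window outside time grid")
    if t_on - t[0] < 60.0:
        raise ValueError("time grid must provide >= 60 s of pre-light baseline")
    amp = 0.0 if (gt.cccp or gt.pump_amplitude == 0) else gt.pump_amplitude
    dev = np.zeros_like(t)
    light = (t >= t_on) & (t <= t_off)
    dev[light] = -amp * (1.0 - np.exp(-(t[light] - t_on) / gt.tau_on))
    dev_off = -amp * (1.0 - np.exp(-(t_off - t_on) / gt.tau_on))
    after = t > t_off
    dev[after] = dev_off * np.exp(-(t[after] - t_off) / gt.tau_on)
    pH = gt.baseline_pH + gt.drift_rate * t + dev
    if gt.noise_sigma > 0:
        rng = np.random.default_rng(gt.seed)
        pH = pH + rng.normal(0.0, gt.noise_sigma, pH.shape)
    return PumpAssayTrace(
        times=t,
        pH=pH,
        light_on=t_on,
        light_off=t_off,
        construct=gt.construct,
        cccp=gt.cccp,
        initial_pH=gt.baseline_pH,
    )


# ---------------------------------------------------------------------------
# pyranine proton release / uptake trace
# ---------------------------------------------------------------------------

@dataclass
class PyranineGroundTruth:
    """True parameters behind a simulated pyranine ΔA450 transient.

    Proton release acidifies the solvent (ΔA450 drops, tau_release) and
    re-uptake restores it (tau_uptake); the trace is a negative-going
    biexponential dip normalised so its depth equals ``amplitude``.
    """

    tau_release: float = 1.5  # ms
    tau_uptake: float = 47.0  # ms
    amplitude: float = 0.01  # peak |dA450|
    baseline_offset: float = 0.0
    noise_sigma: float = 0.05  # fraction of amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tau_uptake > self.tau_release > 0:
            raise ValueError("require tau_uptake > tau_release > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def biphasic_dip_time(tau_release: float, tau_uptake: float) -> float:
    """Time of the minimum of exp(-t/tau_u) - exp(-t/tau_r) (ms)."""
    if abs(tau_release - tau_uptake) < 1e-12:
        raise ValueError("degenerate biexponential: tau_release == tau_uptake")
    return np.log(tau_uptake / tau_release) / (1.0 / tau_release - 1.0 / tau_uptake)


def pyranine_model(t, tau_release: float, tau_uptake: float, amplitude: float) -> np.ndarray:
    """Noiseless pyranine transient, normalised to dip depth = amplitude."""
    t = np.asarray(t, dtype=float)
    shape = np.exp(-t / tau_uptake) - np.exp(-t / tau_release)
    t_star = biphasic_dip_time(tau_release, tau_uptake)
    peak = np.exp(-t_star / tau_uptake) - np.exp(-t_star / tau_release)
    return -amplitude * shape / peak


def default_pyranine_time_grid() -> np.ndarray:
    return np.geomspace(0.1, 1000.0, 300)


def generate_pyranine_trace(
    gt: PyranineGroundTruth,
    time_grid=None,
) -> ProtonFluxTrace:
    """Simulate the background-subtracted pyranine ΔA450 transient."""
    t = default_pyranine_time_grid() if time_grid is None else np.asarray(
        time_grid, dtype=float
    )
    signal = pyranine_model(t, gt.tau_release, gt.tau_uptake, gt.amplitude)
    signal = signal + gt.baseline_offset
    if gt.noise_sigma > 0:
        rng = np.random.default_rng(gt.seed)
        signal = signal + rng.normal(0.0, gt.noise_sigma * gt.amplitude, signal.shape)
    return ProtonFluxTrace(times=t, delta_a450=signal, has_pyranine=True, n_averaged=1000)
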