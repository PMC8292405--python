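"""Proton-flux analysis: pyranine release/uptake kinetics and cell-suspension
pump assays with their pharmacological controls.

Sign convention, enforced end-to-end: proton release acidifies the solvent,
so pyranine ΔA450 goes negative and the suspension pH decreases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .containers import ProtonFluxTrace, PumpAssayTrace
from .kinetics import PhotocycleFit
from .synth import biphasic_dip_time, pyranine_model

logger = logging.getLogger(__name__)

SIGN_CONVENTION = "negative dA450 = acidification = proton release"


@dataclass
class ProtonKineticsResult:
    """Release/uptake time constants from a biphasic pyranine transient."""

    tau_release: float  # ms
    tau_uptake: float   # ms
    amplitude: float    # dip depth, |dA450|
    tau_release_stderr: float
    tau_uptake_stderr: float
    residual_rms: float
    degenerate: bool = False
    sign_convention: str = SIGN_CONVENTION

    def __post_init__(self) -> None:
        if not self.tau_uptake > self.tau_release > 0:
            raise ValueError("require tau_uptake > tau_release > 0")


@dataclass
class PumpVerdict:
    """Is a construct a light-driven proton pump, and on what evidence."""

    construct: str
    amplitude: float       # pH units, positive = light-induced acidification
    noise_floor: float     # s.d. of pre-light baseline residuals
    is_pump: bool
    control_ratios: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.is_pump and not self.amplitude > 3 * self.noise_floor:
            raise ValueError("is_pump requires amplitude > 3 x noise floor")


def subtract_background(
    with_pyranine: ProtonFluxTrace, without_pyranine: ProtonFluxTrace
) -> ProtonFluxTrace:
    """Remove dye-independent absorbance changes (pointwise subtraction).

    If the grids differ, the background is linearly interpolated onto the
    signal grid; disjoint grids are an error.
    """
    t = with_pyranine.times
    if without_pyranine.times.shape == t.shape and np.allclose(without_pyranine.times, t):
        bg = without_pyranine.delta_a450
    else:
        if without_pyranine.times[-1] < t[0] or without_pyranine.times[0] > t[-1]:
            raise ValueError("signal and background time grids are disjoint")
        bg = np.interp(t, without_pyranine.times, without_pyranine.delta_a450)
    return ProtonFluxTrace(
        times=t.copy(),
        delta_a450=with_pyranine.delta_a450 - bg,
        has_pyranine="derived",
        n_averaged=with_pyranine.n_averaged,
    )


def fit_proton_kinetics(trace: ProtonFluxTrace) -> ProtonKineticsResult:
    """Fit the two-phase release/uptake model to a pyranine transient.

    Model: ΔA450(t) = -A (exp(-t/tau_uptake) - exp(-t/tau_release)),
    normalised so A is the dip depth.  The trace must be biphasic and
    negative-going; a positive-going (sign-flipped) trace is rejected
    rather than silently refitted, because the sign carries the physics.
    Fitting raw (non background-subtracted) traces is refused.
    """
    if trace.has_pyranine is False:
        raise ValueError("trace has no pyranine signal to fit")
    t = trace.times
    y = trace.delta_a450
    y0 = y - np.median(y[t >= t[-1] / 3])  # late-time baseline
    dip = float(np.min(y0))
    bump = float(np.max(y0))
    if dip >= 0 or abs(dip) <= abs(bump):
        raise ValueError(
            "no biphasic negative-going signal: expected a dip below baseline "
            f"({SIGN_CONVENTION})"
        )
    i_min = int(np.argmin(y0))
    t_min = t[i_min]
    if i_min == 0 or i_min == t.size - 1:
        raise ValueError("dip on the edge of the time window: cannot fit recovery")

    def model(params: np.ndarray) -> np.ndarray:
        log_tr, log_tu, amp, offset = params
        return pyranine_model(t, np.exp(log_tr), np.exp(log_tu), amp) + offset

    def residuals(params: np.ndarray) -> np.ndarray:
        return model(params) - y

    x0 = np.array([np.log(t_min / 2.0), np.log(t_min * 5.0), abs(dip), float(np.median(y0[:3]))])
    result = least_squares(residuals, x0, method="trf", max_nfev=2000)
    log_tr, log_tu, amp, _ = result.x
    taus = np.sort([np.exp(log_tr), np.exp(log_tu)])
    res = residuals(result.x)
    rms = float(np.sqrt(np.mean(res**2)))

    dof = max(res.size - 4, 1)
    s2 = float(np.sum(res**2)) / dof
    try:
        cov = s2 * np.linalg.inv(result.jac.T @ result.jac)
        stderr_log = np.sqrt(np.maximum(np.diag(cov)[:2], 0.0))
    except np.linalg.LinAlgError:
        stderr_log = np.array([np.nan, np.nan])
    order = np.argsort([log_tr, log_tu])
    stderr = taus * stderr_log[order]

    degenerate = bool(taus[1] / taus[0] < 1.5)
    if degenerate:
        logger.warning("release/uptake time constants nearly collapsed: %s", taus)
    return ProtonKineticsResult(
        tau_release=float(taus[0]),
        tau_uptake=float(taus[1]),
        amplitude=float(abs(amp)),
        tau_release_stderr=float(stderr[0]),
        tau_uptake_stderr=float(stderr[1]),
        residual_rms=rms,
        degenerate=degenerate,
    )


@dataclass
class ConsistencyReport:
    """Comparison of proton-flux timing with photocycle intermediates."""

    release_ratio: float  # tau_release / tau(O-formation = M-decay)
    uptake_ratio: float   # tau_uptake / tau(O-decay)
    tolerance_factor: float
    consistent: bool


def check_photocycle_consistency(
    kinetics: ProtonKineticsResult,
    fit: PhotocycleFit,
    tolerance_factor: float = 5.0,
) -> ConsistencyReport:
    """Test whether proton release/uptake coincide with O-state formation/decay.

    Release is compared to the M-decay time constant (which forms O) and
    uptake to the O-decay constant; "consistent" means both ratios fall
    within [1/tolerance_factor, tolerance_factor].  The ratios are always
    reported, the verdict is a convention (the comparison is order-of-
    magnitude, not exact).
    """
    tau_m = fit.tau("M")
    tau_o = fit.tau("O")
    release_ratio = kinetics.tau_release / tau_m
    uptake_ratio = kinetics.tau_uptake / tau_o
    ok = all(
        1.0 / tolerance_factor <= r <= tolerance_factor
        for r in (release_ratio, uptake_ratio)
    )
    return ConsistencyReport(
        release_ratio=float(release_ratio),
        uptake_ratio=float(uptake_ratio),
        tolerance_factor=float(tolerance_factor),
        consistent=bool(ok),
    )


def _baseline_stats(trace: PumpAssayTrace, min_baseline_s: float = 30.0):
    """Linear fit to the pre-light segment; returns (slope, intercept, sd)."""
    pre = trace.times < trace.light_on
    if np.count_nonzero(pre) < 2 or (trace.light_on - trace.times[0]) < min_baseline_s:
        raise ValueError(f"pre-light baseline shorter than {min_baseline_s} s")
    tb, yb = trace.times[pre], trace.pH[pre]
    slope, intercept = np.polyfit(tb, yb, 1)
    sd = float(np.std(yb - (slope * tb + intercept)))
    return float(slope), float(intercept), sd


def pump_amplitude(trace: PumpAssayTrace) -> tuple[float, float]:
    """Light-induced acidification amplitude and baseline noise floor.

    Amplitude = (linearly extrapolated baseline) - (minimum pH during
    light), positive = acidification.  The minimum is taken on a lightly
    boxcar-smoothed trace (window ~5% of the light period): the raw
    per-sample minimum is a max-of-noise statistic that would sit near
    +3 sigma even for a pump-free trace.
    """
    slope, intercept, sd = _baseline_stats(trace)
    light = (trace.times >= trace.light_on) & (trace.times <= trace.light_off)
    n_light = int(np.count_nonzero(light))
    w = max(3, (n_light // 20) | 1)
    smooth = np.convolve(trace.pH, np.ones(w) / w, mode="same")
    # exclude the half-window at the trace edges where the boxcar is truncated
    valid = light.copy()
    valid[: w // 2] = False
    valid[valid.size - w // 2 :] = False
    i = int(np.argmin(np.where(valid, smooth, np.inf)))
    expected = slope * trace.times[i] + intercept
    return float(expected - smooth[i]), sd


def analyze_pump_assay(
    traces: list[PumpAssayTrace],
    cccp_abolition_ratio: float = 0.2,
) -> dict[str, PumpVerdict]:
    """Verdict per construct from untreated traces and optional controls.

    A construct counts as a proton pump when its untreated amplitude
    exceeds 3x the baseline noise floor AND, if a CCCP-treated trace of the
    same construct is present, CCCP reduces the amplitude below
    ``cccp_abolition_ratio`` of the untreated one.
    """
    untreated = {t.construct: t for t in traces if not t.cccp}
    cccp = {t.construct: t for t in traces if t.cccp}
    if not untreated:
        raise ValueError("need at least one untreated trace")
    verdicts: dict[str, PumpVerdict] = {}
    for construct, trace in untreated.items():
        amp, noise = pump_amplitude(trace)
        ratios: dict[str, float] = {}
        is_pump = amp > 3.0 * noise
        if construct in cccp:
            cccp_amp, _ = pump_amplitude(cccp[construct])
            ratios["cccp"] = cccp_amp / amp if amp != 0 else np.inf
            is_pump = is_pump and abs(cccp_amp) < cccp_abolition_ratio * abs(amp)
        if "empty_vector" in untreated and construct != "empty_vector":
            ev_amp, _ = pump_amplitude(untreated["empty_vector"])
            ratios["empty_vector"] = ev_amp / amp if amp != 0 else np.inf
        verdicts[construct] = PumpVerdict(
            construct=construct,
            amplitude=amp,
            noise_floor=noise,
            is_pump=bool(is_pump),
            control_ratios=ratios,
        )
    return verdicts


def predicted_dip_time(kinetics: ProtonKineticsResult) -> float:
    """Analytic time of the fitted model's minimum, ms."""
    return float(biphasic_dip_time(kinetics.tau_release, kinetics.tau_uptake))
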