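"""pH-dependent spectral analysis: difference spectra, double-pKa fitting,
λmax estimation, isosbestic-point scoring and purity estimation.

Acid titration of a microbial rhodopsin reports the protonation state of the
Schiff-base counterion(s): protonating the primary counterion red-shifts the
visible band, a second protonation event at lower pH can shift it again.
The difference absorbance at two informative wavelengths versus pH is fitted
with a sum of two base-10 logistic (Henderson–Hasselbalch) terms sharing the
pKa values across wavelengths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .containers import TitrationSeries

logger = logging.getLogger(__name__)

DEFAULT_FIT_WAVELENGTHS = (516.0, 591.0)


@dataclass
class DoublePKaFit:
    """Two-site Henderson–Hasselbalch decomposition of titration data.

    ``amplitudes[w]`` holds (a1, a2): the absorbance change completed by the
    first (pka1) and second (pka2) protonation event at wavelength ``w``.
    """

    pka1: float  # higher pKa (first protonation on acidification)
    pka2: float
    amplitudes: dict[float, tuple[float, float]]
    baselines: dict[float, float]
    pka1_stderr: float
    pka2_stderr: float
    fitted_wavelengths: tuple[float, ...]
    residual_rms: float
    degenerate: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pka1 > self.pka2:
            raise ValueError("pka1 must exceed pka2")


def double_hh(pH, pka1: float, pka2: float, a1: float, a2: float, baseline: float = 0.0):
    """Two-transition Henderson–Hasselbalch curve.

    value = baseline + a1/(1 + 10^(pH - pka1)) + a2/(1 + 10^(pH - pka2)).
    Each logistic term is the protonated fraction of one site, so the signal
    grows as pH decreases; with a1 and a2 of one sign the curve is monotone.
    """
    pH = np.asarray(pH, dtype=float)
    return (
        baseline
        + a1 / (1.0 + 10.0 ** (pH - pka1))
        + a2 / (1.0 + 10.0 ** (pH - pka2))
    )


def difference_spectra(series: TitrationSeries) -> np.ndarray:
    """Spectra minus the reference-pH spectrum, row per pH.

    The row at the reference pH is identically zero.  Exact subtraction:
    adding any constant spectrum to every pH leaves the result unchanged.
    """
    ref = series.spectra[series.reference_index]
    return series.spectra - ref[None, :]


def values_at_wavelengths(
    series: TitrationSeries, wavelengths, differenced: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (difference) absorbance at nearest-grid wavelengths.

    Returns (actual wavelengths used, matrix of shape (n_pH, n_wavelengths)).
    """
    data = difference_spectra(series) if differenced else series.spectra
    used, cols = [], []
    for w in np.atleast_1d(wavelengths):
        i = int(np.argmin(np.abs(series.wavelengths - float(w))))
        used.append(float(series.wavelengths[i]))
        cols.append(data[:, i])
    return np.array(used), np.column_stack(cols)


def fit_double_pka(
    data,
    wavelengths=DEFAULT_FIT_WAVELENGTHS,
    pH=None,
    init_pkas=None,
    max_nfev: int = 2000,
) -> DoublePKaFit:
    """Global two-pKa fit of difference absorbance versus pH.

    ``data`` is either a :class:`TitrationSeries` (difference values at the
    requested wavelengths are extracted at the nearest grid points) or an
    (n_pH, n_wavelengths) array accompanied by ``pH``.  The two pKa values
    are shared across wavelengths; amplitudes and baseline are
    per-wavelength and solved linearly at every iteration (variable
    projection).  Output is always ordered pka1 > pka2.
    """
    if isinstance(data, TitrationSeries):
        used_wl, values = values_at_wavelengths(data, wavelengths)
        pH = data.pH_values
    else:
        values = np.atleast_2d(np.asarray(data, dtype=float))
        if values.shape[0] == 1:
            values = values.T
        if pH is None:
            raise ValueError("pH values required when fitting a raw array")
        pH = np.asarray(pH, dtype=float)
        used_wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    if pH.size < 6:
        raise ValueError("need >= 6 pH points to constrain a double-pKa fit")
    if values.shape[0] != pH.size:
        raise ValueError("data rows must match pH values")

    flags: list[str] = []
    lo, hi = float(np.min(pH)), float(np.max(pH))
    if init_pkas is None:
        init_pkas = (lo + 0.67 * (hi - lo), lo + 0.33 * (hi - lo))

    def design(pkas: np.ndarray) -> np.ndarray:
        p1 = 1.0 / (1.0 + 10.0 ** (pH - pkas[0]))
        p2 = 1.0 / (1.0 + 10.0 ** (pH - pkas[1]))
        return np.column_stack([p1, p2, np.ones_like(pH)])

    def solve_linear(pkas: np.ndarray) -> np.ndarray:
        X = design(pkas)
        coef, *_ = np.linalg.lstsq(X, values, rcond=None)
        return coef  # (3, n_wl): a1, a2, baseline per wavelength

    def residuals(pkas: np.ndarray) -> np.ndarray:
        return (values - design(pkas) @ solve_linear(pkas)).ravel()

    # constrain the search to one unit beyond the sampled range: a pKa far
    # outside it is indistinguishable from the baseline (degenerate column).
    # Deterministic multi-start guards against the local minimum where one
    # transition saturates against the range boundary.
    span = hi - lo
    starts = [np.clip(np.asarray(init_pkas, dtype=float), lo - 0.9, hi + 0.9)]
    for f1, f2 in ((0.67, 0.33), (0.85, 0.5), (0.5, 0.15), (0.75, 0.1)):
        starts.append(np.array([lo + f1 * span, lo + f2 * span]))
    result = None
    for x0 in starts:
        candidate = least_squares(
            residuals, x0, bounds=(lo - 1.0, hi + 1.0), method="trf", max_nfev=max_nfev
        )
        if result is None or candidate.cost < result.cost - 1e-15:
            result = candidate
    if result.status <= 0:
        flags.append("fit did not converge")
        logger.warning("double-pKa fit did not converge: %s", result.message)
    pkas = result.x
    coef = solve_linear(pkas)
    res = values - design(pkas) @ coef
    rms = float(np.sqrt(np.mean(res**2)))

    dof = max(res.size - (2 + coef.size), 1)
    s2 = float(np.sum(res**2)) / dof
    try:
        cov = s2 * np.linalg.inv(result.jac.T @ result.jac)
        stderr = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        stderr = np.array([np.nan, np.nan])

    order = np.argsort(pkas)[::-1]  # pka1 = larger
    pkas, stderr, coef_t = pkas[order], stderr[order], coef[[order[0], order[1], 2], :]

    for pk in pkas:
        if not lo < pk < hi:
            flags.append(f"pKa {pk:.2f} outside sampled pH range: poorly constrained")
            warnings.warn(flags[-1], RuntimeWarning)
            stderr = stderr + abs(pk - np.clip(pk, lo, hi))  # inflate honestly

    # degeneracy: collapsed pKa's or a vanishing transition amplitude
    amp_scale = float(np.max(np.abs(coef_t[:2, :]))) or 1.0
    degenerate = bool(
        abs(pkas[0] - pkas[1]) < 0.05
        or np.any(np.max(np.abs(coef_t[:2, :]), axis=1) < 0.02 * amp_scale)
    )
    if degenerate:
        flags.append("degenerate: pKa values collapsed or one amplitude ~ 0")

    amplitudes = {
        float(w): (float(coef_t[0, j]), float(coef_t[1, j])) for j, w in enumerate(used_wl)
    }
    baselines = {float(w): float(coef_t[2, j]) for j, w in enumerate(used_wl)}
    return DoublePKaFit(
        pka1=float(pkas[0]),
        pka2=float(pkas[1]),
        amplitudes=amplitudes,
        baselines=baselines,
        pka1_stderr=float(stderr[0]),
        pka2_stderr=float(stderr[1]),
        fitted_wavelengths=tuple(float(w) for w in used_wl),
        residual_rms=rms,
        degenerate=degenerate,
        flags=flags,
    )


def find_lambda_max(
    wavelengths, spectrum, window: tuple[float, float] | None = None
) -> float:
    """λmax by 3-point parabolic interpolation, reported at 0.1 nm resolution.

    A maximum on the window edge is returned as the edge value with a
    warning (no extrapolation).
    """
    wl = np.asarray(wavelengths, dtype=float)
    y = np.asarray(spectrum, dtype=float)
    if window is not None:
        mask = (wl >= window[0]) & (wl <= window[1])
        wl, y = wl[mask], y[mask]
    if wl.size < 3:
        raise ValueError("need >= 3 points inside the window")
    i = int(np.argmax(y))
    if i == 0 or i == wl.size - 1:
        warnings.warn("spectral maximum on window edge", RuntimeWarning)
        return round(float(wl[i]), 1)
    # parabola through (wl[i-1..i+1], y[i-1..i+1]); vertex offset in grid units
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return round(float(wl[i]), 1)
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    step = 0.5 * (wl[i + 1] - wl[i - 1])
    return round(float(wl[i] + delta * step), 1)


def isosbestic_score(
    diff_matrix,
    wavelengths,
    band: tuple[float, float] = (500.0, 600.0),
    threshold: float = 0.02,
) -> tuple[float, float | None]:
    """Score the presence of an isosbestic point inside a spectral band.

    score(λ) = max over pH of |ΔA(λ)| normalised by the global max |ΔA|; an
    isosbestic point is declared at the minimising λ if its score is below
    ``threshold``.  Returns (minimum score in band, crossing wavelength or
    None).  Scale-invariant by construction.
    """
    diff = np.atleast_2d(np.asarray(diff_matrix, dtype=float))
    wl = np.asarray(wavelengths, dtype=float)
    if diff.shape[0] < 3:
        raise ValueError("need >= 3 difference spectra")
    global_max = float(np.max(np.abs(diff)))
    if global_max == 0:
        raise ValueError("all-zero difference matrix: isosbestic score undefined")
    score = np.max(np.abs(diff), axis=0) / global_max
    mask = (wl >= band[0]) & (wl <= band[1])
    if not np.any(mask):
        raise ValueError("band contains no grid wavelengths")
    i = int(np.argmin(np.where(mask, score, np.inf)))
    best = float(score[i])
    crossing = float(wl[i]) if best < threshold else None
    return best, crossing


@dataclass
class PuritySettings:
    """Extinction coefficients for the A280/Avis purity estimate."""

    epsilon_vis: float = 50_000.0  # M^-1 cm^-1, generic microbial-rhodopsin value
    epsilon_280: float = 67_500.0  # M^-1 cm^-1, sequence-dependent; supply from config
    lambda_vis: float = 533.0

    def __post_init__(self) -> None:
        if self.epsilon_vis <= 0 or self.epsilon_280 <= 0:
            raise ValueError("extinction coefficients must be > 0")


def estimate_purity(a280: float, a_vis: float, settings: PuritySettings) -> float:
    """Rhodopsin-attributable share of A280, in percent.

    purity% = 100 * (a_vis * eps280/eps_vis) / a280 — the fraction of the
    280 nm absorbance explained by chromophore-bearing protein.  Values
    above 100% are clipped with a warning (an extinction-coefficient
    misconfiguration signal).
    """
    if a280 <= 0 or a_vis <= 0:
        raise ValueError("absorbances must be > 0")
    purity = 100.0 * (a_vis * settings.epsilon_280 / settings.epsilon_vis) / a280
    if purity > 100.0:
        warnings.warn(
            f"purity {purity:.1f}% > 100%: check extinction coefficients",
            RuntimeWarning,
        )
        purity = 100.0
    return purity
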