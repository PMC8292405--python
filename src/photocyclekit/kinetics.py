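"""Irreversible sequential photocycle model and global transient-absorption fitting.

The photocycle of a proton-pumping rhodopsin is modelled as a linear chain of
first-order decays

    P1 -> P2 -> ... -> Pn -> ground,

with one decay time constant per intermediate (for the canonical
three-intermediate cycle: K -> M -> O -> ground).  The chain has a closed-form
(Bateman) solution for the occupancies; the measured difference-absorbance
surface is the bilinear product of those occupancies with the
species-associated difference spectra (SADS).  Fitting uses variable
projection: the time constants are the only nonlinear parameters, and the
SADS are re-solved by linear least squares at every iteration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .containers import TransientSurface

logger = logging.getLogger(__name__)

DEFAULT_LABELS = ("K", "M", "O")

#: spectral windows (nm) used to recognise the canonical intermediates
RED_WINDOW = (570.0, np.inf)   # K and O have red-shifted positive bands
BLUE_WINDOW = (-np.inf, 430.0)  # M (deprotonated Schiff base) absorbs blue


@dataclass
class SequentialModel:
    """Linear-chain photocycle scheme: one decay tau (ms) per intermediate."""

    decay_taus: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.decay_taus = np.atleast_1d(np.asarray(self.decay_taus, dtype=float))
        if np.any(self.decay_taus <= 0) or not np.all(np.isfinite(self.decay_taus)):
            raise ValueError("decay time constants must be positive and finite")
        if self.labels is None:
            n = self.decay_taus.size
            self.labels = DEFAULT_LABELS if n == 3 else tuple(
                f"P{i + 1}" for i in range(n)
            )
        self.labels = tuple(self.labels)
        if len(self.labels) != self.decay_taus.size:
            raise ValueError("label count must equal number of intermediates")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    @property
    def n_intermediates(self) -> int:
        return self.decay_taus.size


@dataclass
class PhotocycleFit:
    """Result of a global sequential fit of a transient surface."""

    model: SequentialModel
    sads: np.ndarray            # (n_intermediates, n_wavelengths)
    wavelengths: np.ndarray
    tau_stderr: np.ndarray      # ms, same order as model.decay_taus
    residual_rms: float
    n_iter: int
    converged: bool
    assignments: dict = field(default_factory=dict)

    def tau(self, label: str) -> float:
        """Decay time constant (ms) of the intermediate carrying ``label``."""
        try:
            return float(self.model.decay_taus[self.model.labels.index(label)])
        except ValueError:
            raise KeyError(f"no intermediate labelled {label!r}") from None


@dataclass
class RateReport:
    """Decay rates (ms^-1) in the reporting convention of comparative tables."""

    raw_rates: np.ndarray
    decay_rates: np.ndarray  # round-half-even at `decimals`
    decimals: int = 2


def _chain_rates(taus: np.ndarray) -> np.ndarray:
    """Rates 1/tau with near-degenerate pairs perturbed to avoid the
    removable singularity of the Bateman denominators."""
    k = 1.0 / np.asarray(taus, dtype=float)
    kmax = np.max(k)
    for i in range(k.size):
        for j in range(i):
            if abs(k[i] - k[j]) < 1e-9 * kmax:
                warnings.warn(
                    f"near-degenerate time constants (components {j} and {i}); "
                    "perturbing by 1e-6 relative",
                    RuntimeWarning,
                    stacklevel=3,
                )
                k[i] *= 1.0 + 1e-6
    return k


def sequential_occupancies(
    model: SequentialModel,
    times,
    excited_fraction: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form occupancies of the irreversible chain.

    Parameters
    ----------
    model : the chain scheme (taus in ms).
    times : evaluation times, ms, > 0.
    excited_fraction : initial occupancy of the first intermediate.

    Returns
    -------
    occupancies : (n_intermediates, n_times) array.
    ground : (n_times,) recovered-ground population; at every time
        ``occupancies.sum(axis=0) + ground == excited_fraction``.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t <= 0):
        raise ValueError("times must be > 0")
    if not 0 < excited_fraction <= 1:
        raise ValueError("excited_fraction must be in (0, 1]")
    k = _chain_rates(model.decay_taus)
    n = k.size
    occ = np.zeros((n, t.size))
    # Bateman solution for A1 -> A2 -> ... with c1(0) = excited_fraction
    for i in range(n):
        prefac = excited_fraction * np.prod(k[:i])
        acc = np.zeros_like(t)
        for j in range(i + 1):
            denom = np.prod([k[l] - k[j] for l in range(i + 1) if l != j])
            acc += np.exp(-k[j] * t) / denom
        occ[i] = prefac * acc
    ground = excited_fraction - occ.sum(axis=0)
    return occ, ground


def compose_surface(
    occupancies: np.ndarray,
    sads: np.ndarray,
    wavelengths,
    times,
    meta: dict | None = None,
) -> TransientSurface:
    """Assemble ΔA(λ, t) = SADSᵀ · occupancies as a :class:`TransientSurface`."""
    occupancies = np.asarray(occupancies, dtype=float)
    sads = np.asarray(sads, dtype=float)
    if sads.shape[0] != occupancies.shape[0]:
        raise ValueError(
            f"sads has {sads.shape[0]} rows but occupancies {occupancies.shape[0]}"
        )
    delta_A = sads.T @ occupancies
    return TransientSurface(
        wavelengths=np.asarray(wavelengths, dtype=float),
        times=np.asarray(times, dtype=float),
        delta_A=delta_A,
        meta=dict(meta or {}),
    )


def _solve_sads(delta_A: np.ndarray, occ: np.ndarray) -> np.ndarray:
    """Linear least-squares SADS for fixed occupancies: ΔA ≈ SADSᵀ·occ."""
    coeff, _, rank, _ = np.linalg.lstsq(occ.T, delta_A.T, rcond=None)
    if rank < occ.shape[0]:
        raise np.linalg.LinAlgError(
            "rank-deficient SADS solve: too many intermediates for these data"
        )
    return coeff  # (n_intermediates, n_wavelengths)


def fit_global_sequential(
    surface: TransientSurface,
    n_intermediates: int = 3,
    init_taus=None,
    excited_fraction: float = 1.0,
    wavelengths=None,
    max_nfev: int = 400,
    seed: int | None = None,
) -> PhotocycleFit:
    """Globally fit the sequential model to a transient surface.

    The decay time constants are optimised in log space (positivity by
    construction) with the SADS eliminated by linear least squares at each
    step (variable projection).  Time constants are returned sorted
    ascending with the canonical labels applied in that order.

    Parameters
    ----------
    surface : measured or simulated ΔA(λ, t).
    n_intermediates : chain length (3 for the canonical K/M/O cycle).
    init_taus : optional initial time constants, ms; default log-equispaced
        across the interior of the time grid.
    wavelengths : optional subset of wavelengths (nm) to restrict the fit to,
        e.g. ``(400, 540, 600)`` for the classical three-trace procedure.
    seed : accepted for interface symmetry; the default optimisation is
        deterministic and does not consume randomness.
    """
    if n_intermediates < 1:
        raise ValueError("n_intermediates must be >= 1")
    t = surface.times
    if np.log10(t[-1] / t[0]) < 2:
        raise ValueError("time grid must span at least two decades")
    delta_A = surface.delta_A
    wl = surface.wavelengths
    if wavelengths is not None:
        idx = sorted(
            {int(np.argmin(np.abs(wl - float(w)))) for w in np.atleast_1d(wavelengths)}
        )
        wl = wl[idx]
        delta_A = delta_A[idx]

    if init_taus is None:
        span = np.geomspace(t[0] * 3.0, t[-1] / 3.0, n_intermediates + 2)
        init_taus = span[1:-1]
    init_taus = np.sort(np.atleast_1d(np.asarray(init_taus, dtype=float)))
    if init_taus.size != n_intermediates:
        raise ValueError("init_taus length must equal n_intermediates")

    def occ_of(log_taus: np.ndarray) -> np.ndarray:
        m = SequentialModel(np.exp(log_taus), labels=tuple(str(i) for i in range(n_intermediates)))
        occ, _ = sequential_occupancies(m, t, excited_fraction)
        return occ

    def residuals(log_taus: np.ndarray) -> np.ndarray:
        occ = occ_of(log_taus)
        sads = _solve_sads(delta_A, occ)
        return (delta_A - sads.T @ occ).ravel()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = least_squares(
            residuals,
            np.log(init_taus),
            method="trf",
            x_scale="jac",
            max_nfev=max_nfev,
        )
    log_taus = result.x
    taus = np.exp(log_taus)
    occ = occ_of(log_taus)
    sads = _solve_sads(delta_A, occ)
    res = delta_A - sads.T @ occ
    rms = float(np.sqrt(np.mean(res**2)))

    # covariance of log-taus from the variable-projection Jacobian
    ndata = res.size
    dof = max(ndata - (n_intermediates + sads.size), 1)
    s2 = float(np.sum(res**2)) / dof
    try:
        jtj = result.jac.T @ result.jac
        cov = s2 * np.linalg.inv(jtj)
        stderr_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        stderr_log = np.full(n_intermediates, np.nan)
    tau_stderr = taus * stderr_log  # delta method for tau = exp(log tau)

    order = np.argsort(taus)
    taus = taus[order]
    sads = sads[order]
    tau_stderr = tau_stderr[order]

    labels = DEFAULT_LABELS if n_intermediates == 3 else tuple(
        f"P{i + 1}" for i in range(n_intermediates)
    )
    converged = bool(result.status > 0)
    if not converged:
        logger.warning("global sequential fit did not converge: %s", result.message)
    return PhotocycleFit(
        model=SequentialModel(taus, labels=labels),
        sads=sads,
        wavelengths=wl,
        tau_stderr=tau_stderr,
        residual_rms=rms,
        n_iter=int(result.nfev),
        converged=converged,
    )


def _band_max(sads_row: np.ndarray, wl: np.ndarray, window: tuple[float, float]) -> float:
    mask = (wl >= window[0]) & (wl <= window[1])
    if not np.any(mask):
        return 0.0
    return float(np.max(sads_row[mask]))


def assign_intermediates(fit: PhotocycleFit, band_threshold: float = 0.1) -> PhotocycleFit:
    """Attach K/M/O labels to a 3-intermediate fit from spectral evidence.

    A component counts as red-positive (blue-positive) when its maximum SADS
    value in the >= 570 nm (<= 430 nm) window exceeds ``band_threshold``
    times the global |SADS| maximum.  The earliest red-positive component is
    K, the blue-dominant component is M, the latest red-positive component
    is O.  Components matching no window are labelled "unassigned" — never
    silently guessed.  A blue band on the fastest component is labelled M
    but flagged as a non-canonical ordering.
    """
    if fit.model.n_intermediates != 3:
        raise ValueError("intermediate assignment requires a 3-intermediate fit")
    wl = fit.wavelengths
    scale = float(np.max(np.abs(fit.sads)))
    if scale == 0:
        scale = 1.0
    red = np.array([_band_max(row, wl, RED_WINDOW) for row in fit.sads]) / scale
    blue = np.array([_band_max(row, wl, BLUE_WINDOW) for row in fit.sads]) / scale

    labels = ["unassigned"] * 3
    evidence: dict = {"red_band": red.tolist(), "blue_band": blue.tolist()}
    blue_pos = [i for i in range(3) if blue[i] >= band_threshold]
    if blue_pos:
        m_idx = max(blue_pos, key=lambda i: blue[i])
        labels[m_idx] = "M"
    else:
        m_idx = None
    red_pos = [i for i in range(3) if red[i] >= band_threshold and i != m_idx]
    if red_pos:
        labels[min(red_pos)] = "K"
        if max(red_pos) != min(red_pos):
            labels[max(red_pos)] = "O"
    non_canonical = labels != ["K", "M", "O"]
    if non_canonical:
        logger.warning("non-canonical intermediate ordering: %s", labels)
    evidence["non_canonical"] = non_canonical
    evidence["labels"] = list(labels)

    return PhotocycleFit(
        model=SequentialModel(fit.model.decay_taus, labels=_uniquify(labels)),
        sads=fit.sads,
        wavelengths=fit.wavelengths,
        tau_stderr=fit.tau_stderr,
        residual_rms=fit.residual_rms,
        n_iter=fit.n_iter,
        converged=fit.converged,
        assignments=evidence,
    )


def _uniquify(labels: list[str]) -> tuple[str, ...]:
    out, seen = [], {}
    for lab in labels:
        if lab in seen:
            seen[lab] += 1
            out.append(f"{lab}_{seen[lab]}")
        else:
            seen[lab] = 0
            out.append(lab)
    return tuple(out)


def tau_to_rate(tau: float, decimals: int = 2) -> tuple[float, float]:
    """Convert a decay time constant (ms) to a rate (ms^-1).

    Returns ``(raw, rounded)`` where ``raw = 1/tau`` exactly and ``rounded``
    applies round-half-even at ``decimals`` places, the convention used when
    tabulating M- and O-decay rates across rhodopsins.
    """
    tau = float(tau)
    if tau <= 0:
        raise ValueError("tau must be > 0")
    raw = 1.0 / tau
    return raw, round(raw, decimals)


def rate_report(model: SequentialModel, decimals: int = 2) -> RateReport:
    """Decay rates for every intermediate of a fitted scheme."""
    pairs = [tau_to_rate(t, decimals) for t in model.decay_taus]
    return RateReport(
        raw_rates=np.array([p[0] for p in pairs]),
        decay_rates=np.array([p[1] for p in pairs]),
        decimals=decimals,
    )


def traces_at(surface: TransientSurface, wavelengths) -> dict[float, np.ndarray]:
    """Extract per-wavelength time traces at the nearest grid points.

    Returns a mapping {actual grid wavelength: trace}; requesting 541 nm on
    a 5 nm grid returns (and reports) the 540 nm row.
    """
    out: dict[float, np.ndarray] = {}
    lo, hi = surface.wavelengths[0], surface.wavelengths[-1]
    for w in np.atleast_1d(wavelengths):
        w = float(w)
        if w < lo or w > hi:
            raise ValueError(f"wavelength {w} nm outside grid span [{lo}, {hi}]")
        i = int(np.argmin(np.abs(surface.wavelengths - w)))
        out[float(surface.wavelengths[i])] = surface.delta_A[i].copy()
    return out
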