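"""Retinal isomer quantification from A360 oxime chromatograms.

Retinal extracted as its oxime elutes as separate 15-syn / 15-anti peaks per
isomer (Ts/Ta for all-trans).  Composition is obtained by integrating each
peak above a local linear baseline, converting areas to molar amounts with
per-oxime extinction coefficients at 360 nm, and pooling the syn and anti
peaks of each isomer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import Chromatogram, PeakWindow


@dataclass
class IsomerComposition:
    """Molar isomer fractions with the raw areas behind them."""

    fractions: dict[str, float]        # per isomer, sum to 1
    percent: dict[str, int]            # rounded to integer for reporting
    areas: dict[str, float]            # raw per-peak (per oxime label)
    epsilon_used: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {total})")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be >= 0")


def integrate_peaks(
    chromatogram: Chromatogram, fringe_fraction: float = 0.1
) -> dict[str, float]:
    """Trapezoidal peak areas above per-window linear baselines.

    The baseline of each window is a straight line through its endpoint
    regions: it is least-squares fitted to the samples in the outer
    ``fringe_fraction`` of the window at each end (falling back to the two
    endpoint samples when the fringes are empty), so a single noisy sample
    cannot tilt it.  A window whose net area is negative is zeroed with a
    warning.
    """
    if not chromatogram.peak_windows:
        raise ValueError("chromatogram has no peak windows configured")
    rt = chromatogram.retention_times
    y = chromatogram.a360
    areas: dict[str, float] = {}
    for w in chromatogram.peak_windows:
        mask = (rt >= w.start) & (rt <= w.end)
        if np.count_nonzero(mask) < 3:
            raise ValueError(f"window {w.label} covers fewer than 3 samples")
        x = rt[mask]
        seg = y[mask]
        fringe = fringe_fraction * (x[-1] - x[0])
        edge = (x <= x[0] + fringe) | (x >= x[-1] - fringe)
        if np.count_nonzero(edge) >= 4:
            slope, intercept = np.polyfit(x[edge], seg[edge], 1)
        else:
            slope = (seg[-1] - seg[0]) / (x[-1] - x[0])
            intercept = seg[0] - slope * x[0]
        baseline = slope * x + intercept
        area = float(np.trapezoid(seg - baseline, x))
        if area < 0:
            if area < -1e-12:  # below that it is numerically zero, not a dip
                warnings.warn(
                    f"window {w.label}: negative net area ({area:.3g}); zeroed",
                    RuntimeWarning,
                )
            area = 0.0
        areas[w.label] = area
    return areas


def composition_from_areas(
    areas: dict[str, float],
    epsilon_table: dict[str, float],
    pooling: dict[str, str],
) -> IsomerComposition:
    """Extinction-corrected, syn/anti-pooled isomer composition.

    molar amount of a peak is area / epsilon; each isomer's amount is the
    sum over its oxime peaks (``pooling`` maps oxime label -> isomer).
    A missing extinction coefficient is a hard error — silently assuming
    one would bias the composition.
    """
    unmapped = [label for label in areas if label not in pooling]
    if unmapped:
        raise ValueError(f"peaks not mapped to an isomer: {unmapped}")
    missing = [label for label in areas if label not in epsilon_table]
    if missing:
        raise ValueError(f"no extinction coefficient for peaks: {missing}")
    amounts: dict[str, float] = {}
    eps_used: dict[str, float] = {}
    for label, area in areas.items():
        eps = float(epsilon_table[label])
        if eps <= 0:
            raise ValueError(f"extinction coefficient for {label} must be > 0")
        eps_used[label] = eps
        isomer = pooling[label]
        amounts[isomer] = amounts.get(isomer, 0.0) + area / eps
    total = sum(amounts.values())
    if total <= 0:
        raise ValueError("total integrated amount is zero: no peaks found")
    fractions = {iso: amt / total for iso, amt in amounts.items()}
    percent = {iso: round(100.0 * f) for iso, f in fractions.items()}
    return IsomerComposition(
        fractions=fractions, percent=percent, areas=dict(areas), epsilon_used=eps_used
    )


def quantify(
    chromatogram: Chromatogram,
    epsilon_table: dict[str, float],
    pooling: dict[str, str] | None = None,
) -> IsomerComposition:
    """Integrate, epsilon-correct and pool in one deterministic step.

    ``pooling`` defaults to the isomer attribution carried by the
    chromatogram's peak windows.
    """
    if pooling is None:
        pooling = {w.label: w.isomer for w in chromatogram.peak_windows}
    areas = integrate_peaks(chromatogram)
    return composition_from_areas(areas, epsilon_table, pooling)


def equal_epsilon_table(labels, value: float = 1.0) -> dict[str, float]:
    """Uniform extinction table for when true per-oxime values are unknown.

    Using equal coefficients assumes all oximes absorb identically at
    360 nm, which is only approximately true — prefer measured values.
    """
    warnings.warn(
        "using equal extinction coefficients for all oxime peaks; "
        "composition is area-weighted, not molar-weighted",
        UserWarning,
    )
    return {str(l): float(value) for l in labels}
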