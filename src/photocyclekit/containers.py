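"""Shared in-memory containers for measured (or simulated) quantities.

All spectroscopic axes are in nm, kinetic time axes in ms, pump-assay time
axes in s; absorbance quantities are dimensionless (ΔA or A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _strictly_increasing(x: np.ndarray, name: str) -> None:
    if x.size > 1 and not np.all(np.diff(x) > 0):
        raise ValueError(f"{name} must be strictly increasing")


@dataclass
class TransientSurface:
    """Flash-induced difference-absorbance surface ΔA(λ, t).

    ``delta_A`` has shape (n_wavelengths, n_times); row i is the time trace
    at ``wavelengths[i]``.
    """

    wavelengths: np.ndarray  # nm, strictly increasing
    times: np.ndarray        # ms, strictly increasing, > 0
    delta_A: np.ndarray      # (n_wavelengths, n_times)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = _as_1d(self.wavelengths, "wavelengths")
        self.times = _as_1d(self.times, "times")
        _strictly_increasing(self.wavelengths, "wavelengths")
        _strictly_increasing(self.times, "times")
        if np.any(self.times <= 0):
            raise ValueError("times must be > 0")
        self.delta_A = np.asarray(self.delta_A, dtype=float)
        if self.delta_A.shape != (self.wavelengths.size, self.times.size):
            raise ValueError(
                f"delta_A shape {self.delta_A.shape} does not match grids "
                f"({self.wavelengths.size}, {self.times.size})"
            )
        if not np.all(np.isfinite(self.delta_A)):
            raise ValueError("delta_A contains non-finite entries")


@dataclass
class TitrationSeries:
    """Absorption spectra recorded at a list of pH values."""

    pH_values: np.ndarray    # one per spectrum
    wavelengths: np.ndarray  # nm
    spectra: np.ndarray      # (n_pH, n_wavelengths), absorbance
    reference_pH: float

    def __post_init__(self) -> None:
        self.pH_values = _as_1d(self.pH_values, "pH_values")
        self.wavelengths = _as_1d(self.wavelengths, "wavelengths")
        _strictly_increasing(self.wavelengths, "wavelengths")
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.shape != (self.pH_values.size, self.wavelengths.size):
            raise ValueError("spectra shape does not match pH and wavelength grids")
        self.reference_pH = float(self.reference_pH)
        if not np.any(np.isclose(self.pH_values, self.reference_pH)):
            raise ValueError(f"reference_pH {self.reference_pH} not in pH_values")

    @property
    def reference_index(self) -> int:
        return int(np.argmin(np.abs(self.pH_values - self.reference_pH)))


@dataclass
class PeakWindow:
    """Integration window of one oxime peak on the retention-time axis."""

    label: str   # e.g. "Ts" (all-trans 15-syn) or "Ta" (all-trans 15-anti)
    isomer: str  # e.g. "all-trans", "13-cis"
    start: float  # min
    end: float    # min

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"window {self.label}: end must exceed start")


@dataclass
class Chromatogram:
    """HPLC trace of retinal oximes monitored at 360 nm."""

    retention_times: np.ndarray  # min, strictly increasing
    a360: np.ndarray             # absorbance at 360 nm
    adaptation_state: Literal["dark", "light"] = "dark"
    peak_windows: list[PeakWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.retention_times = _as_1d(self.retention_times, "retention_times")
        _strictly_increasing(self.retention_times, "retention_times")
        self.a360 = _as_1d(self.a360, "a360")
        if self.a360.size != self.retention_times.size:
            raise ValueError("a360 and retention_times length mismatch")
        lo, hi = self.retention_times[0], self.retention_times[-1]
        windows = sorted(self.peak_windows, key=lambda w: w.start)
        for w in windows:
            if w.start < lo or w.end > hi:
                raise ValueError(f"window {w.label} outside retention-time span")
        for a, b in zip(windows, windows[1:]):
            if b.start < a.end:
                raise ValueError(f"windows {a.label} and {b.label} overlap")


@dataclass
class ProtonFluxTrace:
    """Transient absorbance of the pH indicator pyranine at 450 nm.

    Sign convention: negative ΔA450 = solvent acidification = proton release.
    """

    times: np.ndarray       # ms
    delta_a450: np.ndarray  # ΔA
    has_pyranine: bool | str = True  # True / False / "derived" after subtraction
    n_averaged: int = 1

    def __post_init__(self) -> None:
        self.times = _as_1d(self.times, "times")
        _strictly_increasing(self.times, "times")
        self.delta_a450 = _as_1d(self.delta_a450, "delta_a450")
        if self.delta_a450.size != self.times.size:
            raise ValueError("delta_a450 and times length mismatch")


@dataclass
class PumpAssayTrace:
    """pH of an illuminated cell suspension over time."""

    times: np.ndarray  # s
    pH: np.ndarray
    light_on: float    # s
    light_off: float   # s
    construct: Literal["omr2", "empty_vector"] = "omr2"
    cccp: bool = False
    initial_pH: float | None = None

    def __post_init__(self) -> None:
        self.times = _as_1d(self.times, "times")
        _strictly_increasing(self.times, "times")
        self.pH = _as_1d(self.pH, "pH")
        if self.pH.size != self.times.size:
            raise ValueError("pH and times length mismatch")
        if np.any((self.pH < 0) | (self.pH > 14)):
            raise ValueError("pH values outside [0, 14]")
        if not (self.times[0] <= self.light_on < self.light_off <= self.times[-1]):
            raise ValueError("light window must lie within the trace span")
        if self.initial_pH is None:
            self.initial_pH = float(self.pH[0])
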