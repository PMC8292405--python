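"""CSV / YAML / JSON interchange.

All tabular data travel as UTF-8 CSV with unit-suffixed column names; CSV
round-trips preserve full float precision (17 significant digits).
Surfaces are supported in two layouts:

* long — columns ``wavelength_nm, time_ms, delta_A``;
* wide — one row per wavelength, first column ``wavelength_nm``, remaining
  headers the time values in ms.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import Chromatogram, PeakWindow, ProtonFluxTrace, PumpAssayTrace, TitrationSeries, TransientSurface

FLOAT_FMT = "%.17g"


def _check_numeric(df: pd.DataFrame, path) -> None:
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or missing value at row {bad[0] + 2}, column {col!r}"
            )


def write_surface_csv(surface: TransientSurface, path, layout: str = "wide") -> None:
    path = Path(path)
    if layout == "wide":
        df = pd.DataFrame(surface.delta_A, columns=[repr(float(t)) for t in surface.times])
        df.insert(0, "wavelength_nm", surface.wavelengths)
        df.to_csv(path, index=False, float_format=FLOAT_FMT)
    elif layout == "long":
        wl, t = np.meshgrid(surface.wavelengths, surface.times, indexing="ij")
        pd.DataFrame(
            {
                "wavelength_nm": wl.ravel(),
                "time_ms": t.ravel(),
                "delta_A": surface.delta_A.ravel(),
            }
        ).to_csv(path, index=False, float_format=FLOAT_FMT)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_surface_csv(path, layout: str | None = None, meta: dict | None = None) -> TransientSurface:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if layout is None:
        layout = "long" if set(df.columns) >= {"wavelength_nm", "time_ms", "delta_A"} else "wide"
    _check_numeric(df, path)
    df = df.astype(float)
    if layout == "long":
        wide = df.pivot(index="wavelength_nm", columns="time_ms", values="delta_A")
        wide = wide.sort_index().sort_index(axis=1)
        return TransientSurface(
            wavelengths=wide.index.to_numpy(),
            times=wide.columns.to_numpy(),
            delta_A=wide.to_numpy(),
            meta=dict(meta or {}),
        )
    wl = df["wavelength_nm"].to_numpy()
    times = np.array([float(c) for c in df.columns if c != "wavelength_nm"])
    delta_A = df.drop(columns="wavelength_nm").to_numpy()
    return TransientSurface(wavelengths=wl, times=times, delta_A=delta_A, meta=dict(meta or {}))


def write_titration_csv(series: TitrationSeries, path) -> None:
    """Wide layout: wavelength_nm column + one ``pH_<value>`` column per spectrum."""
    df = pd.DataFrame(
        series.spectra.T, columns=[f"pH_{repr(float(p))}" for p in series.pH_values]
    )
    df.insert(0, "wavelength_nm", series.wavelengths)
    df.attrs["reference_pH"] = series.reference_pH
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    sidecar = Path(path).with_suffix(".meta.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"reference_pH": float(series.reference_pH)}, fh)


def read_titration_csv(path) -> TitrationSeries:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _check_numeric(df, path)
    df = df.astype(float)
    ph_cols = [c for c in df.columns if c.startswith("pH_")]
    pH = np.array([float(c[3:]) for c in ph_cols])
    sidecar = path.with_suffix(".meta.yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            reference_pH = float(yaml.safe_load(fh)["reference_pH"])
    else:
        reference_pH = float(np.max(pH))
    return TitrationSeries(
        pH_values=pH,
        wavelengths=df["wavelength_nm"].to_numpy(),
        spectra=df[ph_cols].to_numpy().T,
        reference_pH=reference_pH,
    )


def write_trace_csv(times, values, path, time_col: str, value_col: str) -> None:
    pd.DataFrame({time_col: np.asarray(times), value_col: np.asarray(values)}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def _read_two_columns(path, time_col: str, value_col: str):
    df = pd.read_csv(path, dtype=str)
    for col in (time_col, value_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    _check_numeric(df[[time_col, value_col]], path)
    return df[time_col].astype(float).to_numpy(), df[value_col].astype(float).to_numpy()


def write_chromatogram_csv(chrom: Chromatogram, path) -> None:
    write_trace_csv(chrom.retention_times, chrom.a360, path, "rt_min", "a360")


def read_chromatogram_csv(path, windows: list[PeakWindow] | None = None,
                          adaptation_state: str = "dark") -> Chromatogram:
    rt, a360 = _read_two_columns(path, "rt_min", "a360")
    return Chromatogram(
        retention_times=rt,
        a360=a360,
        adaptation_state=adaptation_state,
        peak_windows=list(windows or []),
    )


def write_flux_trace_csv(trace: ProtonFluxTrace, path) -> None:
    write_trace_csv(trace.times, trace.delta_a450, path, "time_ms", "delta_a450")


def read_flux_trace_csv(path, has_pyranine=True, n_averaged: int = 1) -> ProtonFluxTrace:
    t, v = _read_two_columns(path, "time_ms", "delta_a450")
    return ProtonFluxTrace(times=t, delta_a450=v, has_pyranine=has_pyranine, n_averaged=n_averaged)


def write_pump_trace_csv(trace: PumpAssayTrace, path) -> None:
    write_trace_csv(trace.times, trace.pH, path, "time_s", "pH")
    with open(Path(path).with_suffix(".meta.yaml"), "w") as fh:
        yaml.safe_dump(
            {
                "light_on_s": float(trace.light_on),
                "light_off_s": float(trace.light_off),
                "construct": trace.construct,
                "cccp": bool(trace.cccp),
            },
            fh,
        )


def read_pump_trace_csv(path, meta: dict | None = None) -> PumpAssayTrace:
    path = Path(path)
    t, pH = _read_two_columns(path, "time_s", "pH")
    if meta is None:
        sidecar = path.with_suffix(".meta.yaml")
        if not sidecar.exists():
            raise ValueError(f"{path}: no condition metadata (sidecar {sidecar} missing)")
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
    return PumpAssayTrace(
        times=t,
        pH=pH,
        light_on=float(meta["light_on_s"]),
        light_off=float(meta["light_off_s"]),
        construct=meta.get("construct", "omr2"),
        cccp=bool(meta.get("cccp", False)),
    )


def windows_from_yaml(path) -> list[PeakWindow]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        PeakWindow(
            label=str(w["label"]),
            isomer=str(w["isomer"]),
            start=float(w["start_min"]),
            end=float(w["end_min"]),
        )
        for w in raw["windows"]
    ]


def windows_to_yaml(windows: list[PeakWindow], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "windows": [
                    {
                        "label": w.label,
                        "isomer": w.isomer,
                        "start_min": float(w.start),
                        "end_min": float(w.end),
                    }
                    for w in windows
                ]
            },
            fh,
        )


def ground_truth_to_yaml(gt, path) -> None:
    """Serialize any ground-truth dataclass (Gaussian bands included)."""

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump({"type": type(gt).__name__, "params": encode(gt)}, fh)


def to_json(obj, path=None):
    """JSON-encode result dataclasses (numpy arrays become lists)."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, (set, tuple)):
            return list(o)
        raise TypeError(f"cannot serialize {type(o)}")

    text = json.dumps(obj, default=default, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
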