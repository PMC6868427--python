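"""Table readers/writers (CSV, comma-separated, header required, UTF-8).

Mixing times and ζ delays travel in milliseconds and chemical shifts in ppm
at the file boundary; everything is converted to SI on read.  All writers
round-trip losslessly through the corresponding reader.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exchange import CHANNELS, DecayDataset, ExchangeFitResult
from .melting import MeltCurve
from .populations import Trace1D
from .pucker import CouplingMeasurement

__all__ = [
    "read_decay_csv", "write_decay_csv",
    "read_coupling_csv", "write_coupling_csv",
    "read_peak_csv", "write_peak_csv",
    "read_trace_csv", "write_trace_csv",
    "read_melt_csv", "write_melt_csv",
    "write_fit_report",
]

_DECAY_COLS = ["residue_id", "experiment", "channel", "mixing_time_ms",
               "intensity", "intensity_err"]


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_decay_csv(path) -> list[DecayDataset]:
    """Read a decay table into per-(residue, channel) datasets."""
    df = pd.read_csv(path)
    _require(df, _DECAY_COLS[:5], path)
    bad = set(df["channel"]) - set(CHANNELS)
    if bad:
        raise ValueError(f"{path}: unknown channels {sorted(bad)}")
    out = []
    for (rid, channel), grp in df.groupby(["residue_id", "channel"], sort=False):
        grp = grp.sort_values("mixing_time_ms")
        err = None
        if "intensity_err" in grp.columns and grp["intensity_err"].notna().all():
            err = grp["intensity_err"].to_numpy(float)
        out.append(DecayDataset(
            residue_id=str(rid), channel=str(channel),
            mixing_time=grp["mixing_time_ms"].to_numpy(float) / 1e3,
            intensity=grp["intensity"].to_numpy(float),
            intensity_err=err))
    return out


def write_decay_csv(datasets: list[DecayDataset], path) -> None:
    rows = []
    for d in datasets:
        exp = "ZZ" if d.channel in ("AA", "BB") else "T1"
        for i in range(len(d)):
            rows.append({
                "residue_id": d.residue_id, "experiment": exp,
                "channel": d.channel,
                "mixing_time_ms": d.mixing_time[i] * 1e3,
                "intensity": d.intensity[i],
                "intensity_err": (d.intensity_err[i]
                                  if d.intensity_err is not None else np.nan)})
    pd.DataFrame(rows, columns=_DECAY_COLS).to_csv(path, index=False)


def read_coupling_csv(path) -> list[CouplingMeasurement]:
    df = pd.read_csv(path)
    _require(df, ["residue_id", "s_cross", "s_diag"], path)
    out = []
    for _, row in df.iterrows():
        zeta = (float(row["zeta_ms"]) / 1e3
                if "zeta_ms" in df.columns and pd.notna(row.get("zeta_ms"))
                else 0.01305)
        detected = bool(row["detected"]) if "detected" in df.columns else True
        out.append(CouplingMeasurement(
            residue_id=str(row["residue_id"]), s_cross=float(row["s_cross"]),
            s_diag=float(row["s_diag"]), zeta=zeta, detected=detected))
    return out


def write_coupling_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_peak_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["condition", "probe", "fold", "volume"], path)
    return df


def write_peak_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_trace_csv(path) -> dict[str, Trace1D]:
    """Trace table (condition, ppm, intensity) → {condition: Trace1D}."""
    df = pd.read_csv(path)
    _require(df, ["ppm", "intensity"], path)
    if "condition" not in df.columns:
        df = df.assign(condition="trace")
    return {str(cond): Trace1D(axis=grp["ppm"].to_numpy(float),
                               intensity=grp["intensity"].to_numpy(float))
            for cond, grp in df.groupby("condition", sort=False)}


def write_trace_csv(traces: dict[str, Trace1D], path) -> None:
    frames = [pd.DataFrame({"condition": cond, "ppm": tr.axis,
                            "intensity": tr.intensity})
              for cond, tr in traces.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_melt_csv(path) -> list[MeltCurve]:
    df = pd.read_csv(path)
    _require(df, ["temperature_C", "absorbance", "cycle_id"], path)
    keys = ["cycle_id"] + (["case"] if "case" in df.columns else [])
    curves = []
    for key, grp in df.groupby(keys, sort=False):
        cyc = key[0] if isinstance(key, tuple) else key
        grp = grp.sort_values("temperature_C")
        wl = float(grp["wavelength_nm"].iloc[0]) if "wavelength_nm" in grp.columns else 260.0
        curves.append(MeltCurve.from_celsius(
            grp["temperature_C"].to_numpy(float),
            grp["absorbance"].to_numpy(float),
            wavelength=wl, cycle_id=str(cyc)))
    return curves


def write_melt_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_fit_report(fits: list[ExchangeFitResult], path, seed: int | None = None) -> None:
    """Per-residue exchange fit report JSON."""
    report = {}
    for f in fits:
        report[f.residue_id] = {
            "k_f": f.params.k_f, "k_b": f.params.k_b,
            "r1_a": f.params.r1_a, "r1_b": f.params.r1_b,
            "k_ex": f.k_ex, "p_1B": f.params.p_a, "p_2B": f.params.p_b,
            "errors": dict(f.param_errors) if f.param_errors else None,
            "rss": f.residual_sum_squares, "n_mc": f.n_mc, "seed": seed,
        }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
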