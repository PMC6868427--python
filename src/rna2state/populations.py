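"""Fold-population estimation from peak volumes and 1D lineshape fits.

In slow exchange each fold gives its own resonance, so the fractional
occupancies follow directly from relative peak volumes:
p_1B = V_1B / (V_1B + V_2B).  When only a 1D trace is available (e.g. an
imino resonance pair across a titration), the two components are first
separated by a two-Lorentzian + constant-baseline fit and integrated
analytically (area = amplitude · π · FWHM / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FoldPopulations",
    "Trace1D",
    "LorentzianPeak",
    "TwoLorentzianFit",
    "TitrationSummary",
    "estimate_populations",
    "fit_two_lorentzians",
    "titration_summary",
]


@dataclass(frozen=True)
class FoldPopulations:
    """Fractional occupancies of the 1B and 2B folds under one condition."""

    condition: str
    p_1B: float
    p_2B: float
    err_1B: float | None = None
    err_2B: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_1B <= 1.0 and 0.0 <= self.p_2B <= 1.0):
            raise ValueError("populations must lie in [0, 1]")
        if abs(self.p_1B + self.p_2B - 1.0) > 1e-12:
            raise ValueError("populations must sum to 1")


@dataclass(frozen=True)
class Trace1D:
    """1D slice: chemical-shift axis (ppm, uniform grid) and intensities."""

    axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.axis, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("axis and intensity must be 1-D arrays of equal length")
        if x.size < 32:
            raise ValueError("trace needs >= 32 points")
        d = np.diff(x)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")
        object.__setattr__(self, "axis", x)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class LorentzianPeak:
    position: float
    fwhm: float
    amplitude: float

    @property
    def area(self) -> float:
        return self.amplitude * np.pi * self.fwhm / 2.0


@dataclass(frozen=True)
class TwoLorentzianFit:
    peaks: tuple[LorentzianPeak, LorentzianPeak]
    baseline: float
    residual_sd: float
    merged: bool


@dataclass(frozen=True)
class TitrationSummary:
    populations: tuple[FoldPopulations, ...]
    direction: str
    monotonic: bool


def estimate_populations(table: pd.DataFrame,
                         condition: str | None = None) -> FoldPopulations:
    """Populations from peak volumes of one (condition, probe) group.

    ``table`` needs columns ``fold`` (1B|2B) and ``volume``; ``volume_err``
    is optional and propagated to first order:
    σ(p_1B) = √((V_2B·σ_1B)² + (V_1B·σ_2B)²) / (V_1B+V_2B)².
    """
    folds = set(table["fold"])
    if folds != {"1B", "2B"}:
        raise ValueError(f"need exactly one row per fold 1B and 2B, got folds {sorted(folds)}")
    if len(table) != 2:
        raise ValueError("need exactly one row per fold")
    row_1b = table[table["fold"] == "1B"].iloc[0]
    row_2b = table[table["fold"] == "2B"].iloc[0]
    v1, v2 = float(row_1b["volume"]), float(row_2b["volume"])
    if v1 < 0 or v2 < 0:
        raise ValueError("volumes must be non-negative")
    total = v1 + v2
    if total <= 0:
        raise ValueError("zero total volume")
    err_1b = err_2b = None
    if "volume_err" in table.columns and table["volume_err"].notna().all():
        e1, e2 = float(row_1b["volume_err"]), float(row_2b["volume_err"])
        err = np.hypot(v2 * e1, v1 * e2) / total**2
        err_1b = err_2b = float(err)
    if condition is None:
        condition = str(row_1b.get("condition", ""))
    p1 = v1 / total
    return FoldPopulations(condition=condition, p_1B=p1, p_2B=1.0 - p1,
                           err_1B=err_1b, err_2B=err_2b)


def _two_lorentzians(x, a1, x1, w1, a2, x2, w2, c):
    return (a1 / (1.0 + ((x - x1) / (w1 / 2.0)) ** 2)
            + a2 / (1.0 + ((x - x2) / (w2 / 2.0)) ** 2) + c)


def fit_two_lorentzians(trace: Trace1D,
                        init_positions: tuple[float, float],
                        init_fwhm: float | None = None) -> TwoLorentzianFit:
    """Fit I(x) = Σᵢ Aᵢ/(1+((x−x₀ᵢ)/(wᵢ/2))²) + c to a 1D trace.

    The two initial positions must lie inside the axis range and be more than
    one grid step apart.  A ``merged`` flag is set when the fitted positions
    are closer than a quarter of the larger FWHM — the two-component areas
    are then not meaningful individually.
    """
    x, y = trace.axis, trace.intensity
    lo, hi = min(x[0], x[-1]), max(x[0], x[-1])
    p1, p2 = init_positions
    step = abs(x[1] - x[0])
    if not (lo <= p1 <= hi and lo <= p2 <= hi):
        raise ValueError("initial positions must lie inside the axis range")
    if abs(p1 - p2) <= step:
        raise ValueError("initial positions must be separated by more than one grid step")
    if init_fwhm is None:
        init_fwhm = max(5 * step, abs(p1 - p2) / 4.0)

    c0 = float(np.min(y))
    amp = lambda p: max(float(np.interp(p, x if x[0] < x[-1] else x[::-1],
                                        y if x[0] < x[-1] else y[::-1]) - c0), 1e-12)
    p0 = [amp(p1), p1, init_fwhm, amp(p2), p2, init_fwhm, c0]
    span = hi - lo
    bounds = ([0.0, lo, step / 2.0, 0.0, lo, step / 2.0, -np.inf],
              [np.inf, hi, span, np.inf, hi, span, np.inf])
    try:
        popt, _ = curve_fit(_two_lorentzians, x, y, p0=p0, bounds=bounds,
                            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"two-Lorentzian fit did not converge: {exc}") from exc

    a1, x1, w1, a2, x2, w2, c = popt
    merged = abs(x1 - x2) < max(w1, w2) / 4.0
    if merged:
        warnings.warn("fitted peaks overlap strongly (merged-peak flag set)",
                      stacklevel=2)
    resid = y - _two_lorentzians(x, *popt)
    return TwoLorentzianFit(
        peaks=(LorentzianPeak(float(x1), float(w1), float(a1)),
               LorentzianPeak(float(x2), float(w2), float(a2))),
        baseline=float(c),
        residual_sd=float(resid.std()),
        merged=bool(merged),
    )


def titration_summary(tables: pd.DataFrame,
                      condition_order: list[str] | None = None,
                      tol: float = 1e-9) -> TitrationSummary:
    """Per-condition populations along an ordered condition series.

    Conditions are taken in ``condition_order`` or, by default, in order of
    first appearance.  The direction report tracks p_2B: "p_2B increasing",
    "p_2B decreasing" or "no change"; ``monotonic`` is False when the series
    changes direction by more than ``tol``.
    """
    if condition_order is None:
        condition_order = list(dict.fromkeys(tables["condition"]))
    if len(condition_order) < 2:
        raise ValueError("titration needs >= 2 conditions")
    pops = []
    for cond in condition_order:
        sub = tables[tables["condition"] == cond]
        if sub.empty:
            raise ValueError(f"condition {cond!r} missing from table")
        pops.append(estimate_populations(sub, condition=cond))
    p2 = np.array([p.p_2B for p in pops])
    diffs = np.diff(p2)
    net = p2[-1] - p2[0]
    if abs(net) <= tol and np.all(np.abs(diffs) <= tol):
        direction = "no change"
    elif net > tol:
        direction = "p_2B increasing"
    elif net < -tol:
        direction = "p_2B decreasing"
    else:
        direction = "no net change"
    monotonic = bool(np.all(diffs >= -tol) or np.all(diffs <= tol))
    return TitrationSummary(populations=tuple(pops), direction=direction,
                            monotonic=monotonic)
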