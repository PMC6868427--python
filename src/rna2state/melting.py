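"""Two-state monomolecular UV-melting analysis.

An absorbance-vs-temperature trace of a unimolecular folder is reduced to the
association degree α(T) — the folded fraction — by fitting sloped linear
baselines in a low-temperature (folded) and a high-temperature (unfolded)
window:

    α(T) = (A_high(T) − A(T)) / (A_high(T) − A_low(T))

α then follows the van't Hoff two-state form

    α(T) = 1 / (1 + exp((ΔH° − T·ΔS°) / (R·T)))

whose two parameters are the enthalpy ΔH° and entropy ΔS° of association
(both negative for a folding transition), with Tm = ΔH°/ΔS° and α(Tm) = ½.
ΔH°/ΔS° are in kJ·mol⁻¹ and kJ·mol⁻¹·K⁻¹; temperatures are Kelvin internally
(°C accepted at the I/O boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "R_GAS_KJ",
    "MeltCurve",
    "AlphaSeries",
    "MeltThermo",
    "association_degree",
    "vant_hoff_alpha",
    "fit_vant_hoff",
    "cycle_average",
]

#: gas constant, kJ·mol⁻¹·K⁻¹
R_GAS_KJ = 8.314e-3


@dataclass(frozen=True)
class MeltCurve:
    """One heating (or cooling) cycle: temperature in K, absorbance in AU."""

    temperature: np.ndarray
    absorbance: np.ndarray
    wavelength: float = 260.0
    cycle_id: str = "cycle1"

    def __post_init__(self) -> None:
        T = np.asarray(self.temperature, dtype=float)
        A = np.asarray(self.absorbance, dtype=float)
        if T.ndim != 1 or T.shape != A.shape:
            raise ValueError("temperature and absorbance must be 1-D arrays of equal length")
        if T.size < 20:
            raise ValueError("melt curve needs >= 20 points")
        if np.any(np.diff(T) <= 0):
            raise ValueError("temperature must be strictly increasing within a cycle")
        object.__setattr__(self, "temperature", T)
        object.__setattr__(self, "absorbance", A)

    @classmethod
    def from_celsius(cls, temperature_c, absorbance, **kw) -> "MeltCurve":
        return cls(np.asarray(temperature_c, dtype=float) + 273.15, absorbance, **kw)


@dataclass(frozen=True)
class AlphaSeries:
    temperature: np.ndarray
    alpha: np.ndarray


@dataclass(frozen=True)
class MeltThermo:
    """Two-state association thermodynamics; Tm = ΔH°/ΔS°."""

    dH: float  # kJ/mol, < 0 for folding
    dS: float  # kJ/(mol K), < 0 for folding
    param_errors: dict | None = None

    @property
    def tm(self) -> float:
        return self.dH / self.dS


def _baseline_windows_default(T: np.ndarray) -> tuple[tuple[float, float], tuple[float, float]]:
    span = T[-1] - T[0]
    return (T[0], T[0] + 0.15 * span), (T[-1] - 0.15 * span, T[-1])


def association_degree(curve: MeltCurve,
                       baseline_windows: tuple[tuple[float, float], tuple[float, float]] | None = None
                       ) -> AlphaSeries:
    """Baseline-correct a melt curve into the association degree α(T).

    ``baseline_windows`` are ((T_lo_min, T_lo_max), (T_hi_min, T_hi_max)) in
    Kelvin; defaults to the lowest/highest 15% of the temperature range.
    Each window must contain >= 5 points and the windows must not overlap.
    α is clipped to [−0.05, 1.05] with a warning when points fall outside.
    """
    T, A = curve.temperature, curve.absorbance
    if baseline_windows is None:
        baseline_windows = _baseline_windows_default(T)
    (lo0, lo1), (hi0, hi1) = baseline_windows
    if lo1 >= hi0:
        raise ValueError("baseline windows overlap")
    m_lo = (T >= lo0) & (T <= lo1)
    m_hi = (T >= hi0) & (T <= hi1)
    if m_lo.sum() < 5 or m_hi.sum() < 5:
        raise ValueError("each baseline window must contain >= 5 points")
    b_lo = np.polyfit(T[m_lo], A[m_lo], 1)
    b_hi = np.polyfit(T[m_hi], A[m_hi], 1)
    A_lo = np.polyval(b_lo, T)
    A_hi = np.polyval(b_hi, T)
    denom = A_hi - A_lo
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("degenerate baselines: folded and unfolded lines coincide")
    alpha = (A_hi - A) / denom
    if np.any(alpha < -0.05) or np.any(alpha > 1.05):
        warnings.warn("association degree outside [-0.05, 1.05]; clipping", stacklevel=2)
    return AlphaSeries(temperature=T, alpha=np.clip(alpha, -0.05, 1.05))


def vant_hoff_alpha(T, dH: float, dS: float):
    """Two-state association degree α(T) = 1/(1 + exp((ΔH° − TΔS°)/(RT)))."""
    T = np.asarray(T, dtype=float)
    return 1.0 / (1.0 + np.exp((dH - T * dS) / (R_GAS_KJ * T)))


def fit_vant_hoff(series: AlphaSeries,
                  n_boot: int = 200, seed: int = 0) -> MeltThermo:
    """Least-squares van't Hoff fit of (ΔH°, ΔS°) to an α(T) series.

    Requires the transition to be sampled through at least [0.2, 0.8] in α.
    Parameter uncertainties come from ``n_boot`` seeded Monte-Carlo refits on
    residual-resampled curves.  Fails if ΔS° >= 0 at the optimum (not a
    folding transition).
    """
    T, a = series.temperature, series.alpha
    if a.min() > 0.2 or a.max() < 0.8:
        raise ValueError("alpha must span at least [0.2, 0.8] for a stable fit")

    # seed: Tm from the 0.5 crossing, |dH| from the transition steepness
    # (dα/dT at Tm = ΔH/(4 R Tm²) under the model)
    order = np.argsort(a)
    tm0 = float(np.interp(0.5, a[order], T[order]))
    i_mid = int(np.argmin(np.abs(T - tm0)))
    sl = slice(max(i_mid - 3, 0), min(i_mid + 4, len(T)))
    slope = np.polyfit(T[sl], a[sl], 1)[0]
    dH0 = float(np.clip(4.0 * R_GAS_KJ * tm0**2 * slope, -3000, -10))
    p0 = [dH0, dH0 / tm0]

    popt, _ = curve_fit(vant_hoff_alpha, T, a, p0=p0, maxfev=20000)
    dH, dS = float(popt[0]), float(popt[1])
    if dS >= 0 or dH >= 0:
        raise RuntimeError(
            f"van't Hoff fit converged to a non-folding optimum (dH={dH:.1f}, dS={dS:.3f})")

    fit_a = vant_hoff_alpha(T, dH, dS)
    resid = a - fit_a
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 2))
    ok = 0
    for i in range(n_boot):
        a_star = fit_a + rng.choice(resid, size=resid.size, replace=True)
        try:
            pb, _ = curve_fit(vant_hoff_alpha, T, a_star, p0=popt, maxfev=5000)
            draws[ok] = pb
            ok += 1
        except RuntimeError:
            continue
    errors = None
    if ok >= 2:
        sds = draws[:ok].std(axis=0, ddof=1)
        tm_draws = draws[:ok, 0] / draws[:ok, 1]
        errors = {"dH": float(sds[0]), "dS": float(sds[1]),
                  "tm": float(tm_draws.std(ddof=1))}
    return MeltThermo(dH=dH, dS=dS, param_errors=errors)


def cycle_average(curves: list[MeltCurve],
                  baseline_windows=None,
                  n_boot: int = 0, seed: int = 0) -> dict:
    """Fit each cycle and report the mean ± sd of Tm across cycles.

    Cycles whose fit fails are excluded with a warning; if all fail, raises.
    Returns {"tm_mean", "tm_sd", "n_cycles", "fits": [MeltThermo, ...]}.
    """
    if len(curves) < 2:
        raise ValueError("cycle averaging needs >= 2 cycles")
    fits, tms = [], []
    for c in curves:
        try:
            series = association_degree(c, baseline_windows)
            th = fit_vant_hoff(series, n_boot=max(n_boot, 2) if n_boot else 2,
                               seed=seed)
            fits.append(th)
            tms.append(th.tm)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"cycle {c.cycle_id} excluded: {exc}", stacklevel=2)
    if not fits:
        raise RuntimeError("all melting cycles failed to fit")
    tms = np.asarray(tms)
    return {"tm_mean": float(tms.mean()),
            "tm_sd": float(tms.std(ddof=1)) if len(tms) > 1 else 0.0,
            "n_cycles": len(fits), "fits": fits}
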