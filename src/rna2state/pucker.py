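"""Ribose sugar-pucker analysis from quantitative-J cross/diagonal ratios.

A quantitative-J H1'(C1')H2' experiment yields, for each residue, a diagonal
peak and (when the coupling is non-zero) a cross peak whose intensity ratio
follows the tangent law

    S_cross / S_diag = -tan²(2π · J · ζ)

with J the three-bond H1'-H2' scalar coupling and ζ the evolution delay.
Because ³J(H1'H2') is large (~8-9 Hz) for the south (C2'-endo) ring pucker and
small (~1 Hz) for north (C3'-endo), a measured J translates linearly into the
fraction of the south conformer under a two-state model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "ZETA_DEFAULT",
    "PuckerLimits",
    "CouplingMeasurement",
    "PuckerResult",
    "ratio_from_j",
    "j_from_ratio",
    "south_fraction",
    "analyze_coupling",
]

#: default evolution delay ζ, seconds (13.05 ms)
ZETA_DEFAULT = 0.01305

#: default |S_cross/S_diag| below which the cross peak is deemed undetected
DETECTION_THRESHOLD = 0.01


@dataclass(frozen=True)
class PuckerLimits:
    """Limiting ³J(H1'H2') couplings of the pure conformers, Hz.

    Defaults: 1.0 Hz for pure north (C3'-endo) and 8.8 Hz for pure south
    (C2'-endo).  Both are configurable; the south default equals the coupling
    of a tetraloop uridine known to be predominantly C2'-endo, a common
    internal reference.
    """

    j_north: float = 1.0
    j_south: float = 8.8

    def __post_init__(self) -> None:
        if self.j_north >= self.j_south:
            raise ValueError("j_north must be < j_south")


@dataclass(frozen=True)
class CouplingMeasurement:
    """Cross/diagonal peak intensities for one residue.

    ``s_cross`` is signed (opposite in sign to the diagonal under the model,
    carried here as a non-positive ratio); ``detected=False`` marks an
    explicitly absent cross peak.
    """

    residue_id: str
    s_cross: float
    s_diag: float
    zeta: float = ZETA_DEFAULT
    detected: bool = True

    def __post_init__(self) -> None:
        if self.s_diag <= 0:
            raise ValueError("s_diag must be positive")
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")

    @property
    def ratio(self) -> float:
        return self.s_cross / self.s_diag


@dataclass(frozen=True)
class PuckerResult:
    residue_id: str
    j_h1h2: float | None
    south_fraction: float
    limits: PuckerLimits
    status: str


def ratio_from_j(j: float, zeta: float = ZETA_DEFAULT) -> float:
    """Forward tangent law: S_cross/S_diag = -tan²(2π·J·ζ).

    Valid for 0 <= j < 1/(4ζ) (≈19.157 Hz at the default ζ); beyond that the
    tangent diverges and the ratio is no longer single-valued.
    """
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    if j < 0:
        raise ValueError("coupling must be non-negative")
    if j >= 1.0 / (4.0 * zeta):
        raise ValueError(
            f"J = {j} Hz at/above the tangent singularity 1/(4ζ) = {1.0 / (4.0 * zeta):.3f} Hz"
        )
    return -math.tan(2.0 * math.pi * j * zeta) ** 2


def j_from_ratio(ratio: float, zeta: float = ZETA_DEFAULT) -> float:
    """Invert the tangent law on the principal branch.

    Returns the unique J in [0, 1/(4ζ)) with ratio_from_j(J) = ratio.
    """
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    if ratio > 0:
        raise ValueError("S_cross/S_diag must be <= 0 under the model")
    return math.atan(math.sqrt(-ratio)) / (2.0 * math.pi * zeta)


def south_fraction(j: float, j_north: float = 1.0, j_south: float = 8.8) -> float:
    """Two-state south/north population from a measured coupling.

    Linear interpolation between the limiting couplings; values outside the
    [j_north, j_south] interval are clamped to [0, 1] with a warning.
    """
    if j_north >= j_south:
        raise ValueError("j_north must be < j_south")
    frac = (j - j_north) / (j_south - j_north)
    if frac < -1e-9 or frac > 1.0 + 1e-9:
        warnings.warn(
            f"coupling {j} Hz outside limiting range [{j_north}, {j_south}] Hz; "
            "south fraction clamped", stacklevel=2)
        frac = min(max(frac, 0.0), 1.0)
    return frac


def analyze_coupling(meas: CouplingMeasurement,
                     limits: PuckerLimits | None = None,
                     detection_threshold: float = DETECTION_THRESHOLD) -> PuckerResult:
    """Full per-residue pucker analysis.

    An absent cross peak (``detected=False`` or |ratio| below the detection
    threshold) is reported as pure north (C3'-endo) with undefined J — the
    noise floor, not a true zero coupling, drives non-detection.
    """
    limits = limits or PuckerLimits()
    absent = (not meas.detected) or abs(meas.ratio) < detection_threshold
    if absent:
        return PuckerResult(
            residue_id=meas.residue_id, j_h1h2=None, south_fraction=0.0,
            limits=limits, status="C3'-endo (no detectable cross peak)")
    if meas.ratio > 0:
        raise ValueError(
            f"{meas.residue_id}: cross peak must be opposite in sign to the diagonal "
            f"(ratio = {meas.ratio:.3g} > 0)")
    j = j_from_ratio(meas.ratio, meas.zeta)
    frac = south_fraction(j, limits.j_north, limits.j_south)
    return PuckerResult(residue_id=meas.residue_id, j_h1h2=j,
                        south_fraction=frac, limits=limits,
                        status="two-state south/north equilibrium")
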