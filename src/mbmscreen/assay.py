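"""Wet-lab readout utilities: FRET inhibition %, IC50, SPR steady-state K_D.

These mirror the analysis applied to the validation experiments: a BACE1
FRET activity assay (inhibition percentage and IC50 from a linear
inhibition–concentration regression) and SPR steady-state affinity fitting
of the 1:1 Langmuir isotherm R(C) = Rmax·C/(K_D + C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FluorescenceMeasurement",
    "SprCurve",
    "DegenerateControlError",
    "Ic50NotBracketedError",
    "SprFitError",
    "inhibition_percent",
    "ic50_linear",
    "spr_steady_state",
]


class DegenerateControlError(ValueError):
    """Control fluorescence did not change (C == C0)."""


class Ic50NotBracketedError(ValueError):
    """The fitted inhibition line never crosses 50% near the data."""


class SprFitError(RuntimeError):
    """Steady-state affinity fit failed or K_D is unidentifiable."""


@dataclass(frozen=True)
class FluorescenceMeasurement:
    """One FRET well: S/S0 with inhibitor after/before reaction, C/C0 the
    no-inhibitor control after/before, at a given inhibitor concentration (μM)."""

    s: float
    s0: float
    c: float
    c0: float
    concentration: float = 0.0

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class SprCurve:
    concentrations: tuple[float, ...]  # μM, sorted ascending
    responses: tuple[float, ...]  # response units at steady state
    rmax: float
    kd: float  # μM
    kd_unit: str = "uM"

    def model_response(self, c):
        return self.rmax * np.asarray(c) / (self.kd + np.asarray(c))


def inhibition_percent(m: FluorescenceMeasurement) -> float:
    """[1 - (S - S0)/(C - C0)] × 100, in percent."""
    if m.c == m.c0:
        raise DegenerateControlError("degenerate control: C equals C0")
    return float((1.0 - (m.s - m.s0) / (m.c - m.c0)) * 100.0)


def ic50_linear(points: list[tuple[float, float]]) -> float:
    """IC50 (μM) from an ordinary least-squares line of inhibition % on
    concentration: the concentration where the fitted line reaches 50%.

    Requires >= 2 points, a positive slope, and the 50% crossing to lie
    within twice the concentration span of the data.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 (concentration, inhibition) points")
    conc = np.array([c for c, _ in points], dtype=float)
    inh = np.array([i for _, i in points], dtype=float)
    slope, intercept = np.polyfit(conc, inh, 1)
    if slope <= 0:
        raise Ic50NotBracketedError("IC50 not bracketed: non-positive slope")
    ic50 = (50.0 - intercept) / slope
    span = conc.max() - conc.min()
    lo, hi = conc.min() - 2 * span, conc.max() + 2 * span
    if not (lo <= ic50 <= hi):
        raise Ic50NotBracketedError(
            f"IC50 not bracketed: crossing at {ic50:.3g} μM, data span "
            f"[{conc.min():.3g}, {conc.max():.3g}] μM")
    return float(ic50)


def spr_steady_state(
    concentrations, responses, *, max_nfev: int = 10_000
) -> SprCurve:
    """Fit the 1:1 steady-state binding isotherm R(C) = Rmax·C/(K_D + C).

    Least squares with the deterministic initialiser Rmax0 = max response,
    K_D0 = median concentration; both parameters constrained positive.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.ndim != 1 or conc.shape != resp.shape or len(conc) < 3:
        raise ValueError("need >= 3 matched concentrations and responses")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if np.any(resp < 0):
        raise ValueError("responses must be non-negative")
    if np.all(resp == 0):
        raise SprFitError("K_D unidentifiable: all responses are zero")
    order = np.argsort(conc)
    conc, resp = conc[order], resp[order]

    def iso(c, rmax, kd):
        return rmax * c / (kd + c)

    p0 = (float(resp.max()), float(np.median(conc)))
    try:
        popt, _ = curve_fit(
            iso, conc, resp, p0=p0, bounds=([0.0, 1e-12], [np.inf, np.inf]),
            max_nfev=max_nfev)
    except RuntimeError as e:
        raise SprFitError(f"steady-state fit did not converge: {e}") from e
    rmax, kd = (float(v) for v in popt)
    return SprCurve(tuple(conc), tuple(resp), rmax, kd)
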