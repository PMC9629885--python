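"""Apparent ADA concentration from a positive-control reference curve.

A monoclonal positive control (PC), carried through the same acid-capture
enrichment as the samples, is titrated on each plate and fitted with a
four-parameter logistic (4PL).  Sample signals are inverse-interpolated off
this curve, multiplied by the assay dilution factor and divided by the
PC's enrichment recovery (about 30%) to back-calculate an apparent serum
concentration.  Because the PC is monoclonal while sample ADA is polyclonal
(and parallelism is not established) the result is semi-quantitative;
signals outside the calibrated range are flagged, never extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ReferenceCurve",
    "ConcentrationResult",
    "four_pl",
    "fit_reference",
    "apparent_concentration",
]

DEFAULT_RECOVERY = 0.30


def four_pl(x, a: float, d: float, c: float, b: float):
    """4PL response ``d + (a - d) / (1 + (x/c)**b)``.

    ``a`` is the zero-concentration asymptote, ``d`` the infinite-
    concentration asymptote, ``c`` the midpoint (EC50) and ``b`` the slope.
    """
    x = np.asarray(x, dtype=float)
    out = d + (a - d) / (1.0 + (x / c) ** b)
    return out if out.ndim else float(out)


def _inverse_four_pl(y, a: float, d: float, c: float, b: float):
    ratio = (a - d) / (np.asarray(y, dtype=float) - d) - 1.0
    return c * ratio ** (1.0 / b)


@dataclass(frozen=True)
class ReferenceCurve:
    """Fitted PC calibration curve with its interpolable range."""

    a: float
    d: float
    c: float
    b: float
    recovery: float
    conc_range: tuple[float, float]
    signal_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0 < self.recovery <= 1:
            raise ValueError("recovery must be in (0, 1]")

    def predict(self, conc):
        return four_pl(conc, self.a, self.d, self.c, self.b)

    def inverse(self, signal):
        return _inverse_four_pl(signal, self.a, self.d, self.c, self.b)


def fit_reference(
    pc_concs, signals, recovery: float = DEFAULT_RECOVERY
) -> ReferenceCurve:
    """Least-squares 4PL fit of the PC calibrators.

    Requires at least five calibrator levels whose replicate-averaged
    signals are strictly monotone in concentration (an immunoassay
    calibration must be invertible); otherwise a ``ValueError`` is raised.
    """
    concs = np.asarray(pc_concs, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if concs.shape != sig.shape or concs.ndim != 1:
        raise ValueError("pc_concs and signals must be matching 1-d arrays")
    if np.any(concs <= 0):
        raise ValueError("calibrator concentrations must be positive")
    levels = np.unique(concs)
    if levels.size < 5:
        raise ValueError("need at least 5 calibrator levels")
    means = np.array([sig[concs == c].mean() for c in levels])
    diffs = np.diff(means)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("calibrator signals are not monotone in concentration")

    a0, d0 = means[0], means[-1]
    c0 = np.sqrt(levels[0] * levels[-1])
    b0 = 1.0  # direction is carried by the a/d ordering

    def resid(p):
        a, d, logc, b = p
        return four_pl(concs, a, d, np.exp(logc), b) - sig

    sol = least_squares(
        resid, x0=[a0, d0, np.log(c0), b0], method="lm", xtol=1e-14, ftol=1e-14
    )
    a, d, b = float(sol.x[0]), float(sol.x[1]), float(sol.x[3])
    c = float(np.exp(sol.x[2]))
    if b < 0:  # canonical orientation: (a, d, b) and (d, a, -b) are identical
        a, d, b = d, a, -b
    s_lo = four_pl(levels[0], a, d, c, b)
    s_hi = four_pl(levels[-1], a, d, c, b)
    return ReferenceCurve(
        a=a,
        d=d,
        c=c,
        b=b,
        recovery=recovery,
        conc_range=(float(levels[0]), float(levels[-1])),
        signal_range=(min(s_lo, s_hi), max(s_lo, s_hi)),
    )


@dataclass(frozen=True)
class ConcentrationResult:
    """Apparent concentration (ng/mL) with its quantitation flag."""

    value: float
    flag: str  # {"ok", "below_quantitation", "above_quantitation"}
    dilution: float
    recovery_corrected: bool


def apparent_concentration(
    signal: float,
    ref: ReferenceCurve,
    dilution: float = 1.0,
    recovery_correct: bool = True,
) -> ConcentrationResult:
    """Inverse-4PL interpolation of one sample signal.

    The interpolated concentration is multiplied by the dilution factor
    and, when ``recovery_correct`` is set, divided by the PC recovery
    fraction to estimate the pre-enrichment serum concentration.  Signals
    outside the calibrated signal range return NaN with a below/above-
    quantitation flag.
    """
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    lo, hi = ref.signal_range
    increasing = ref.predict(ref.conc_range[1]) > ref.predict(ref.conc_range[0])
    if signal < lo or signal > hi:
        below_signal = signal < lo
        below_conc = below_signal if increasing else not below_signal
        flag = "below_quantitation" if below_conc else "above_quantitation"
        return ConcentrationResult(float("nan"), flag, dilution, recovery_correct)
    conc = float(ref.inverse(signal)) * dilution
    if recovery_correct:
        conc /= ref.recovery
    return ConcentrationResult(conc, "ok", dilution, recovery_correct)
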