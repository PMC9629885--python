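"""Curve-quality gating: the confidence-bound flatness test and the
assay signal window.

A K_D from an inhibition curve is only trustworthy when the curve actually
inhibits: the fitted response at the lowest drug dose (highest signal) must
be statistically separated from the response at the highest dose (lowest
signal).  The flatness test asks, at a 99% confidence level by default,
whether the lower bound of the prediction at the minimum observed dose
exceeds the upper bound at the maximum observed dose; overlap means the two
curve ends are not differentiated and the fit fails.  For the best-quality
K_D, both the monophasic and the biphasic fit must pass.

The signal window — the observed signal at the lowest dose divided by the
signal at the highest dose — is the companion descriptive statistic; a
window of at least 4.0 (together with ADA log titer >= 3.0) marks the
regime where K_D estimates were empirically accurate, and is attached as a
reporting annotation, not a hard gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import AffinityCurve
from .fit import BindingFitResults

__all__ = [
    "FlatnessVerdict",
    "SignalWindow",
    "flatness_test",
    "curve_acceptance",
    "signal_window",
]

#: reporting annotations for the empirically reliable regime
SIGNAL_WINDOW_ANNOTATION = 4.0
LOG_TITER_ANNOTATION = 3.0


@dataclass(frozen=True)
class FlatnessVerdict:
    passed: bool
    lower_at_min_dose: float
    upper_at_max_dose: float
    level: float
    model: str

    def __post_init__(self) -> None:
        expect = self.lower_at_min_dose > self.upper_at_max_dose
        if self.passed != expect:
            raise ValueError("passed flag inconsistent with stored bounds")


def flatness_test(
    fit: BindingFitResults, curve: AffinityCurve | None = None, level: float = 0.99
) -> FlatnessVerdict:
    """Confidence-bound separation of the fitted curve's ends.

    Passes iff the lower confidence bound of the mean response at the
    minimum observed dose strictly exceeds the upper bound at the maximum
    observed dose.  Unconverged or covariance-singular fits produce
    infinite bounds and therefore fail.
    """
    curve = curve or fit.curve
    if not fit.converged or not np.all(np.isfinite(fit.cov_log)):
        return FlatnessVerdict(
            passed=False,
            lower_at_min_dose=-np.inf,
            upper_at_max_dose=np.inf,
            level=level,
            model=fit.model,
        )
    _, lo_min, _ = fit.predict_with_bounds(curve.min_dose, level=level)
    _, _, hi_max = fit.predict_with_bounds(curve.max_dose, level=level)
    lower = float(lo_min[0])
    upper = float(hi_max[0])
    return FlatnessVerdict(
        passed=lower > upper,
        lower_at_min_dose=lower,
        upper_at_max_dose=upper,
        level=level,
        model=fit.model,
    )


def curve_acceptance(mono_verdict: FlatnessVerdict, bi_verdict: FlatnessVerdict) -> bool:
    """Both the monophasic and the biphasic fit must pass the flatness test."""
    return mono_verdict.passed and bi_verdict.passed


@dataclass(frozen=True)
class SignalWindow:
    window: float
    signal_low_dose: float
    signal_high_dose: float


def signal_window(curve: AffinityCurve) -> SignalWindow:
    """Observed signal at the lowest dose over the signal at the highest
    dose (replicates averaged).  Raw observations, not fitted values."""
    low = curve.mean_signal_at(curve.min_dose)
    high = curve.mean_signal_at(curve.max_dose)
    if high <= 0:
        raise ValueError("signal at the highest dose must be positive for a window")
    return SignalWindow(window=low / high, signal_low_dose=low, signal_high_dose=high)
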