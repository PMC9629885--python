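"""Longitudinal and cross-sectional reporting over fitted affinity results.

Covers replicate precision of the positive-control K_D, per-patient K_D
trajectories and fold-changes, the monophasic-to-biphasic switch day,
high-affinity proportion trends, and the Pearson correlation between ADA
log titer and log10 K_D (an affinity-maturation study expects this
correlation to be negative: higher titers accompany lower K_D).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .qc import FlatnessVerdict
from .select import ModelChoice

__all__ = [
    "PrecisionSummary",
    "SampleResult",
    "PatientTrajectory",
    "precision_summary",
    "trajectory",
    "kd_titer_correlation",
    "proportion_trend",
]


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrecisionSummary:
    """Replicate precision of a K_D: mean, sample SD, %CV, plus the
    display-rounded values (half-up; mean/SD at ``decimals``, CV integer)."""

    mean: float
    sd: float
    cv_percent: float
    mean_rounded: float
    sd_rounded: float
    cv_rounded: int
    n: int


def precision_summary(kd_values, decimals: int = 1) -> PrecisionSummary:
    """Arithmetic mean, sample (n-1) SD and %CV of replicate K_D values.

    Values must share a unit (e.g. pM).  Display rounding is half-up to
    ``decimals`` places for mean and SD and to an integer for the CV,
    matching conventional bioanalytical reporting.
    """
    values = np.asarray(kd_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 replicate K_D values")
    if np.any(values <= 0):
        raise ValueError("K_D values must be positive")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    cv = 100.0 * sd / mean
    return PrecisionSummary(
        mean=mean,
        sd=sd,
        cv_percent=cv,
        mean_rounded=_round_half_up(mean, decimals),
        sd_rounded=_round_half_up(sd, decimals),
        cv_rounded=int(_round_half_up(cv, 0)),
        n=values.size,
    )


@dataclass(frozen=True)
class SampleResult:
    """Everything the pipeline knows about one fitted sample."""

    sample_id: str
    patient_id: str
    study_day: int
    choice: ModelChoice
    flatness_mono: FlatnessVerdict
    flatness_bi: FlatnessVerdict
    accepted: bool
    signal_window: float
    log10_titer: float = float("nan")
    nab_status: str = "unknown"


@dataclass(frozen=True)
class PatientTrajectory:
    """Time-ordered affinity results for one patient.

    ``fold_change`` is K_D at the first time point divided by K_D at the
    last (a maturing response gives values > 1); by default only samples
    passing curve acceptance contribute, with failing time points retained
    and flagged.  ``first_biphasic_day`` records the switch from a
    monophasic- to a biphasic-best-fit response, if any.
    """

    patient_id: str
    records: tuple[SampleResult, ...]
    fold_change: float
    first_biphasic_day: int | None
    include_flagged: bool = False
    proportion_series: tuple[tuple[int, float], ...] = field(default=())


def trajectory(records: list[SampleResult], include_flagged: bool = False) -> PatientTrajectory:
    """Assemble one patient's trajectory from per-sample results."""
    if not records:
        raise ValueError("no records for trajectory")
    pids = {r.patient_id for r in records}
    if len(pids) != 1:
        raise ValueError(f"records span multiple patients: {sorted(pids)}")
    ordered = tuple(sorted(records, key=lambda r: r.study_day))
    used = [r for r in ordered if include_flagged or r.accepted]
    if used:
        fold = used[0].choice.kd_report / used[-1].choice.kd_report
    else:
        fold = float("nan")
    first_bi = next(
        (r.study_day for r in ordered if r.choice.selected == "biphasic"), None
    )
    props = tuple((r.study_day, r.choice.proportion_high) for r in ordered)
    return PatientTrajectory(
        patient_id=ordered[0].patient_id,
        records=ordered,
        fold_change=fold,
        first_biphasic_day=first_bi,
        include_flagged=include_flagged,
        proportion_series=props,
    )


def kd_titer_correlation(samples, log_kd: bool = True) -> float:
    """Pearson r between ADA log10 titer and (log10) K_D.

    ``samples`` is a sequence of ``(log10_titer, kd)`` pairs with positive
    K_D.  K_D spans decades, so the correlation is taken against log10 K_D
    by default; set ``log_kd=False`` for a plain-scale sensitivity check.
    """
    pairs = [(t, k) for t, k in samples if np.isfinite(t) and np.isfinite(k)]
    if len(pairs) < 3:
        raise ValueError("need at least 3 (titer, kd) pairs")
    titers = np.array([t for t, _ in pairs])
    kds = np.array([k for _, k in pairs])
    if np.any(kds <= 0):
        raise ValueError("K_D values must be positive")
    y = np.log10(kds) if log_kd else kds
    if np.ptp(titers) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(titers, y)
    return float(r)


#: proportion changes smaller than this are called flat
PROPORTION_FLAT_TOL = 0.05


def proportion_trend(trajectories: list[PatientTrajectory]) -> dict[str, dict]:
    """High-affinity proportion over time per patient, with a trend flag.

    The flag compares the last biphasic proportion to the first:
    ``increasing`` / ``decreasing`` when the change exceeds the flat
    tolerance, ``flat`` otherwise.
    """
    out: dict[str, dict] = {}
    for traj in trajectories:
        series = traj.proportion_series
        if len(series) >= 2:
            delta = series[-1][1] - series[0][1]
            if delta > PROPORTION_FLAT_TOL:
                flag = "increasing"
            elif delta < -PROPORTION_FLAT_TOL:
                flag = "decreasing"
            else:
                flag = "flat"
        else:
            flag = "insufficient"
        out[traj.patient_id] = {"series": series, "trend": flag}
    return out
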