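"""End-to-end analysis: fit both models, select, gate, and summarise.

`analyze_curve` runs the full per-sample procedure (monophasic and
biphasic fits, AICc selection, flatness tests, signal window) and
`analyze_study` maps it over a study's curves and assembles per-patient
trajectories and study-level summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curves import AffinityCurve
from .fit import fit_biphasic, fit_monophasic
from .qc import curve_acceptance, flatness_test, signal_window
from .report import PatientTrajectory, SampleResult, kd_titer_correlation, proportion_trend, trajectory
from .select import choose_model

__all__ = ["analyze_curve", "analyze_study", "results_to_frame", "study_summary"]


def analyze_curve(curve: AffinityCurve, level: float = 0.99) -> SampleResult:
    """Full per-sample analysis of one affinity curve."""
    mono = fit_monophasic(curve)
    bi = fit_biphasic(curve)
    choice = choose_model(mono, bi)
    v_mono = flatness_test(mono, curve, level=level)
    v_bi = flatness_test(bi, curve, level=level)
    meta = curve.meta
    return SampleResult(
        sample_id=curve.sample_id,
        patient_id=meta.patient_id if meta else "",
        study_day=meta.study_day if meta else 0,
        choice=choice,
        flatness_mono=v_mono,
        flatness_bi=v_bi,
        accepted=curve_acceptance(v_mono, v_bi),
        signal_window=signal_window(curve).window,
        log10_titer=meta.log10_titer if meta else float("nan"),
        nab_status=meta.nab_status if meta else "unknown",
    )


def analyze_study(
    curves: list[AffinityCurve], level: float = 0.99, include_flagged: bool = False
) -> tuple[list[SampleResult], list[PatientTrajectory]]:
    results = [analyze_curve(c, level=level) for c in curves]
    by_patient: dict[str, list[SampleResult]] = {}
    for r in results:
        by_patient.setdefault(r.patient_id, []).append(r)
    trajectories = [
        trajectory(recs, include_flagged=include_flagged) for recs in by_patient.values()
    ]
    return results, trajectories


def results_to_frame(results: list[SampleResult]) -> pd.DataFrame:
    """Per-sample results table with explicit units in the column names."""
    rows = []
    for r in results:
        c = r.choice
        rows.append(
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "study_day": r.study_day,
                "selected_model": c.selected,
                "prob_mono": c.prob_mono,
                "prob_bi": c.prob_bi,
                "aicc_mono": c.aicc_mono,
                "aicc_bi": c.aicc_bi,
                "kd_report_pM": c.kd_report * 1e12,
                "kd_mono_pM": c.kd_mono * 1e12,
                "kd1_pM": c.kd1 * 1e12,
                "kd2_pM": c.kd2 * 1e12,
                "kd_geo_pM": c.kd_geo * 1e12,
                "proportion_high_pct": 100.0 * c.proportion_high,
                "proportion_low_pct": 100.0 * c.proportion_low,
                "signal_window": r.signal_window,
                "flatness_mono_pass": r.flatness_mono.passed,
                "flatness_bi_pass": r.flatness_bi.passed,
                "accepted": r.accepted,
                "log10_titer": r.log10_titer,
                "nab_status": r.nab_status,
            }
        )
    return pd.DataFrame(rows)


def study_summary(
    results: list[SampleResult], trajectories: list[PatientTrajectory]
) -> dict:
    """Study-level JSON-serialisable summary."""
    pairs = [
        (r.log10_titer, r.choice.kd_report)
        for r in results
        if np.isfinite(r.log10_titer) and r.choice.kd_report > 0
    ]
    try:
        r_log = kd_titer_correlation(pairs, log_kd=True)
        r_plain = kd_titer_correlation(pairs, log_kd=False)
    except ValueError:
        r_log = r_plain = float("nan")
    trends = proportion_trend(trajectories)
    return {
        "n_samples": len(results),
        "n_accepted": sum(r.accepted for r in results),
        "pearson_r_logtiter_logkd": r_log,
        "pearson_r_logtiter_kd": r_plain,
        "patients": {
            t.patient_id: {
                "fold_change": t.fold_change,
                "first_biphasic_day": t.first_biphasic_day,
                "proportion_trend": trends[t.patient_id]["trend"],
                "kd_report_pM_by_day": {
                    int(r.study_day): r.choice.kd_report * 1e12 for r in t.records
                },
                "accepted_by_day": {int(r.study_day): r.accepted for r in t.records},
            }
            for t in trajectories
        },
    }
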