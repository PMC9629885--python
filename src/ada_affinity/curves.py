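"""Data containers for affinity curves and sample metadata, with CSV I/O.

The curve CSV schema (RFC 4180, UTF-8, header mandatory) is::

    sample_id, patient_id, study_day, dose_ng_per_ml, dose_molar, signal, replicate

and the metadata CSV schema::

    sample_id, patient_id, study_day, log10_titer, nab_status, dilution
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SampleMeta", "AffinityCurve", "curves_to_frame", "frame_to_curves", "meta_to_frame"]

CURVE_COLUMNS = [
    "sample_id",
    "patient_id",
    "study_day",
    "dose_ng_per_ml",
    "dose_molar",
    "signal",
    "replicate",
]


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample clinical annotations carried alongside a curve."""

    patient_id: str
    study_day: int
    log10_titer: float = float("nan")
    nab_status: str = "unknown"  # {"positive", "negative", "unknown"}
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.study_day < 0:
            raise ValueError("study_day must be >= 0")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.nab_status not in {"positive", "negative", "unknown"}:
            raise ValueError(f"invalid nab_status {self.nab_status!r}")


@dataclass(frozen=True)
class AffinityCurve:
    """One sample's paired (dose, signal) observations: the unit of fitting.

    Doses are molar.  At least 5 distinct doses are required so that the
    biphasic model (4 parameters) leaves a positive small-sample AICc
    denominator.  Signals are non-negative assay units, one per dose row;
    replicate rows (same dose) are permitted.
    """

    sample_id: str
    doses: np.ndarray
    signals: np.ndarray
    meta: SampleMeta | None = None
    doses_ng_per_ml: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        signals = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "signals", signals)
        if doses.shape != signals.shape or doses.ndim != 1:
            raise ValueError("doses and signals must be 1-d arrays of equal length")
        if not np.all(np.isfinite(doses)) or np.any(doses < 0):
            raise ValueError("doses must be finite and >= 0")
        if not np.all(np.isfinite(signals)) or np.any(signals < 0):
            raise ValueError("signals must be finite and >= 0")
        if np.unique(doses).size < 5:
            raise ValueError("curve needs at least 5 distinct doses")

    def __len__(self) -> int:
        return self.doses.size

    @property
    def min_dose(self) -> float:
        return float(self.doses.min())

    @property
    def max_dose(self) -> float:
        return float(self.doses.max())

    def mean_signal_at(self, dose: float) -> float:
        """Replicate-averaged observed signal at an exact dose value."""
        mask = self.doses == dose
        if not mask.any():
            raise ValueError(f"dose {dose!r} not observed on this curve")
        return float(self.signals[mask].mean())


def curves_to_frame(curves: list[AffinityCurve]) -> pd.DataFrame:
    """Flatten curves into the long-format curve CSV schema."""
    rows = []
    for curve in curves:
        meta = curve.meta
        ng = curve.doses_ng_per_ml
        for i in range(len(curve)):
            rows.append(
                {
                    "sample_id": curve.sample_id,
                    "patient_id": meta.patient_id if meta else "",
                    "study_day": meta.study_day if meta else "",
                    "dose_ng_per_ml": ng[i] if ng is not None else "",
                    "dose_molar": curve.doses[i],
                    "signal": curve.signals[i],
                    "replicate": 1,
                }
            )
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def frame_to_curves(df: pd.DataFrame, meta_df: pd.DataFrame | None = None) -> list[AffinityCurve]:
    """Group a long-format curve table back into AffinityCurve objects.

    Raises ``ValueError`` naming the offending column when the schema is
    malformed, and a join error naming the sample when metadata is missing.
    """
    required = {"sample_id", "dose_molar", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curve table missing column(s): {sorted(missing)}")
    if df.empty:
        raise ValueError("curve table is empty")
    meta_by_sample: dict[str, SampleMeta] = {}
    if meta_df is not None:
        for _, row in meta_df.iterrows():
            meta_by_sample[str(row["sample_id"])] = SampleMeta(
                patient_id=str(row["patient_id"]),
                study_day=int(row["study_day"]),
                log10_titer=float(row.get("log10_titer", float("nan"))),
                nab_status=str(row.get("nab_status", "unknown")),
                dilution=float(row.get("dilution", 1.0)),
            )
    curves = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        meta = None
        if meta_df is not None:
            if str(sample_id) not in meta_by_sample:
                raise KeyError(f"metadata missing for sample {sample_id!r}")
            meta = meta_by_sample[str(sample_id)]
        elif "patient_id" in grp.columns and "study_day" in grp.columns:
            first = grp.iloc[0]
            try:
                meta = SampleMeta(
                    patient_id=str(first["patient_id"]), study_day=int(first["study_day"])
                )
            except (ValueError, TypeError):
                meta = None
        ng = None
        if "dose_ng_per_ml" in grp.columns:
            ng_vals = pd.to_numeric(grp["dose_ng_per_ml"], errors="coerce").to_numpy()
            if np.all(np.isfinite(ng_vals)):
                ng = ng_vals
        curves.append(
            AffinityCurve(
                sample_id=str(sample_id),
                doses=grp["dose_molar"].to_numpy(dtype=float),
                signals=grp["signal"].to_numpy(dtype=float),
                meta=meta,
                doses_ng_per_ml=ng,
            )
        )
    return curves


def meta_to_frame(curves: list[AffinityCurve]) -> pd.DataFrame:
    rows = []
    for curve in curves:
        m = curve.meta
        if m is None:
            continue
        rows.append(
            {
                "sample_id": curve.sample_id,
                "patient_id": m.patient_id,
                "study_day": m.study_day,
                "log10_titer": m.log10_titer,
                "nab_status": m.nab_status,
                "dilution": m.dilution,
            }
        )
    return pd.DataFrame(rows)
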