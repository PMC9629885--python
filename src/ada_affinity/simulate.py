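"""Synthetic affinity-assay generator with an exact mass-balance oracle.

The closed-form response models assume the free drug concentration equals
the dosed concentration (excess-ligand approximation).  This module instead
solves the exact bivalent mass balance at each dose —

    l_tot = L + sum_c sites_c * L / (kd_c + L)

for the free drug ``L`` shared by all antibody clones — and builds the
detected signal from the fraction of each clone carrying at least one free
paratope, ``1 - theta**2`` with ``theta = L/(kd + L)``.  In the dilute limit
(binding sites well below both K_D and every dose) the simulated signal
converges to the closed-form models, which makes the simulator an
independent oracle for them; outside that limit it reproduces the
ligand-depletion bias a real plate would show.

A multi-patient maturation scenario emulating a clinical time course
(apparent K_D falling 20-2000-fold per patient, high-affinity proportion
rising, titers rising) is provided by :func:`default_scenario`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .curves import AffinityCurve, SampleMeta
from .models import DEFAULT_MOLAR_MASS, DoseSpec, to_molar

__all__ = [
    "ClonePopulation",
    "AssayNoiseModel",
    "PatientPlan",
    "StudyScenario",
    "make_dose_series",
    "free_ligand",
    "detectable_fraction",
    "simulate_curve",
    "simulate_study",
    "default_scenario",
]


@dataclass(frozen=True)
class ClonePopulation:
    """One affinity population: total binding-site concentration (molar;
    an IgG clone at concentration c contributes 2c sites) and its true
    per-site dissociation constant."""

    site_conc: float
    kd: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.site_conc < 0:
            raise ValueError("site_conc must be >= 0")
        if not self.kd > 0:
            raise ValueError("kd must be > 0")


@dataclass(frozen=True)
class AssayNoiseModel:
    """Multiplicative log-normal noise with coefficient of variation ``cv``
    plus an additive background signal; ``seed`` makes runs reproducible."""

    cv: float = 0.08
    background: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.background < 0:
            raise ValueError("cv and background must be >= 0")


def make_dose_series(
    top: float = 1000.0,
    fold: float = 5.0,
    n: int = 8,
    unit: str = "ng/mL",
    molar_mass: float = DEFAULT_MOLAR_MASS,
) -> DoseSpec:
    """Serial-dilution dose series ``top / fold**i`` for ``i = 0..n-1``.

    The default reproduces the assay design: eight 5-fold dilutions from
    1000 ng/mL down to 1000/5**7 = 0.0128 ng/mL.
    """
    if not top > 0:
        raise ValueError("top dose must be > 0")
    if not fold > 1:
        raise ValueError("dilution fold must be > 1")
    if n < 2:
        raise ValueError("need at least 2 doses")
    series = top / fold ** np.arange(n, dtype=float)
    molar = to_molar(series, unit, molar_mass) if unit != "M" else series
    return DoseSpec(
        doses=tuple(molar),
        source_unit=unit,
        molar_mass=molar_mass if unit != "M" else None,
        doses_source=tuple(series),
    )


def free_ligand(l_tot: float, site_tot, kd) -> float:
    """Free drug concentration from the exact equilibrium mass balance.

    Solves ``l_tot = L + sum_c sites_c * L / (kd_c + L)`` for the unique
    root ``L`` in ``[0, l_tot]`` (uniqueness follows from the left side
    being strictly increasing in L).  ``site_tot`` and ``kd`` may be
    scalars or matching arrays of clone values sharing one ligand pool.
    """
    sites = np.atleast_1d(np.asarray(site_tot, dtype=float))
    kds = np.atleast_1d(np.asarray(kd, dtype=float))
    if sites.shape != kds.shape:
        raise ValueError("site_tot and kd must have matching shapes")
    if np.any(sites < 0) or np.any(kds <= 0) or l_tot < 0:
        raise ValueError("require l_tot >= 0, site_tot >= 0, kd > 0")
    if l_tot == 0:
        return 0.0
    if sites.sum() == 0:
        return float(l_tot)

    def balance(L: float) -> float:
        return L + float(np.sum(sites * L / (kds + L))) - l_tot

    # balance(0) = -l_tot < 0 and balance(l_tot) >= 0: bracketed root
    return float(brentq(balance, 0.0, l_tot, xtol=1e-300, rtol=1e-15, maxiter=200))


def detectable_fraction(l_free: float, kd: float):
    """Fraction of bivalent antibody with at least one free paratope,
    ``1 - theta**2`` with per-site occupancy ``theta = L/(kd + L)``."""
    if np.any(np.asarray(l_free) < 0) or not kd > 0:
        raise ValueError("require l_free >= 0 and kd > 0")
    theta = np.asarray(l_free, dtype=float) / (kd + np.asarray(l_free, dtype=float))
    out = 1.0 - theta**2
    return out if out.ndim else float(out)


def _noiseless_signals(
    dose_spec: DoseSpec, clones: list[ClonePopulation], scale: float, background: float
) -> np.ndarray:
    sites = np.array([c.site_conc for c in clones])
    kds = np.array([c.kd for c in clones])
    signals = np.empty(len(dose_spec.doses))
    for i, dose in enumerate(dose_spec.doses_molar):
        L = free_ligand(dose, sites, kds)
        # antibody concentration is site_conc/2 (two sites per IgG)
        detected = sum(
            c.site_conc / 2.0 * detectable_fraction(L, c.kd) for c in clones
        )
        signals[i] = background + scale * detected
    return signals


def simulate_curve(
    dose_spec: DoseSpec,
    clones: list[ClonePopulation],
    scale: float,
    noise: AssayNoiseModel,
    sample_id: str = "sim",
    meta: SampleMeta | None = None,
    rng: np.random.Generator | None = None,
) -> AffinityCurve:
    """Simulate one affinity curve.

    Per dose: exact free-drug mass balance over all clones, signal
    ``background + scale * sum_c site_c/2 * (1 - theta_c**2)``, then
    multiplicative log-normal noise at the stated CV (mean-preserving).
    Deterministic given ``noise.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    signals = _noiseless_signals(dose_spec, clones, scale, noise.background)
    if noise.cv > 0:
        sigma = np.sqrt(np.log1p(noise.cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=signals.size)
        signals = signals * factors
    ng = None
    if dose_spec.source_unit == "ng/mL":
        ng = np.asarray(dose_spec.doses_source, dtype=float)
    return AffinityCurve(
        sample_id=sample_id,
        doses=dose_spec.doses_molar.copy(),
        signals=signals,
        meta=meta,
        doses_ng_per_ml=ng,
    )


# ---------------------------------------------------------------------------
# Study scenarios

@dataclass(frozen=True)
class PatientPlan:
    """Ground-truth time course for one patient.

    ``kd_geo`` interpolates geometrically from ``kd_geo_start`` to
    ``kd_geo_end`` across ``days``; the two clones sit at
    ``kd_geo / sqrt(phase_ratio)`` (high affinity) and
    ``kd_geo * sqrt(phase_ratio)`` (low affinity).  The high-affinity share
    of binding sites moves linearly from ``prop_start`` to ``prop_end`` and
    the total site concentration from ``site_start`` to ``site_end``
    (log-linear), emulating a rising titer.
    """

    patient_id: str
    days: tuple[int, ...]
    kd_geo_start: float
    kd_geo_end: float
    prop_start: float
    prop_end: float
    site_start: float = 2e-14
    site_end: float = 8e-14
    phase_ratio: float = 30.0
    titer_start: float = 2.0
    titer_end: float = 4.5

    def truth_at(self, index: int) -> dict:
        frac = index / (len(self.days) - 1) if len(self.days) > 1 else 1.0
        kd_geo = self.kd_geo_start * (self.kd_geo_end / self.kd_geo_start) ** frac
        prop = self.prop_start + (self.prop_end - self.prop_start) * frac
        site = self.site_start * (self.site_end / self.site_start) ** frac
        half = np.sqrt(self.phase_ratio)
        titer = self.titer_start + (self.titer_end - self.titer_start) * frac
        return {
            "day": self.days[index],
            "kd_geo": kd_geo,
            "kd1": kd_geo / half,
            "kd2": kd_geo * half,
            "proportion_high": prop,
            "site_tot": site,
            "log10_titer": titer,
            "nab_status": "positive" if titer >= 3.5 else "negative",
        }


@dataclass(frozen=True)
class StudyScenario:
    """A full multi-patient study: per-patient plans plus shared assay
    settings (dose series, detection scale, noise model)."""

    patients: tuple[PatientPlan, ...]
    dose_spec: DoseSpec
    detection_scale: float = 1e18
    noise: AssayNoiseModel = field(default_factory=AssayNoiseModel)

    def __post_init__(self) -> None:
        for p in self.patients:
            if list(p.days) != sorted(set(p.days)):
                raise ValueError(f"study days must be strictly increasing for {p.patient_id}")


def default_scenario(seed: int = 0, cv: float = 0.08) -> StudyScenario:
    """Seven-patient affinity-maturation scenario.

    Patients 1-4 have >= 4 time points with the high-affinity proportion
    rising; patient 5 has three time points with a flat proportion;
    patients 6-7 contribute two time points each.  True K_D(geo) falls
    monotonically for every patient with per-patient fold-changes between
    20x and 2000x, and log titer rises as affinity matures.
    """
    plans = (
        PatientPlan("P1", (15, 43, 85, 113, 141, 169), 1e-9, 5e-12, 0.30, 0.75),
        PatientPlan("P2", (15, 57, 85, 141, 183), 2e-9, 2e-12, 0.25, 0.70),
        PatientPlan("P3", (29, 85, 113, 169), 6e-10, 3e-11, 0.35, 0.65),
        PatientPlan("P4", (15, 57, 113, 141, 183), 2e-9, 1e-12, 0.30, 0.80),
        PatientPlan("P5", (29, 99, 169), 1e-9, 1e-11, 0.50, 0.50),
        PatientPlan("P6", (15, 141), 5e-10, 1e-11, 0.35, 0.60),
        PatientPlan("P7", (29, 183), 3e-9, 6e-12, 0.30, 0.70),
    )
    return StudyScenario(
        patients=plans,
        dose_spec=make_dose_series(),
        noise=AssayNoiseModel(cv=cv, background=20.0, seed=seed),
    )


def simulate_study(scenario: StudyScenario) -> tuple[list[AffinityCurve], list[dict]]:
    """Simulate every patient/time-point curve of a scenario.

    Returns the curves (with metadata) and a ground-truth record per sample
    (JSON-serialisable).  Per-sample noise streams are spawned from the
    scenario seed, so the whole study is reproducible from one integer.
    """
    seed_seq = np.random.SeedSequence(scenario.noise.seed)
    curves: list[AffinityCurve] = []
    truth: list[dict] = []
    n_samples = sum(len(p.days) for p in scenario.patients)
    children = seed_seq.spawn(n_samples)
    idx = 0
    for plan in scenario.patients:
        for i in range(len(plan.days)):
            t = plan.truth_at(i)
            clones = [
                ClonePopulation(t["site_tot"] * t["proportion_high"], t["kd1"], "high"),
                ClonePopulation(t["site_tot"] * (1 - t["proportion_high"]), t["kd2"], "low"),
            ]
            sample_id = f"{plan.patient_id}_d{t['day']:03d}"
            meta = SampleMeta(
                patient_id=plan.patient_id,
                study_day=t["day"],
                log10_titer=t["log10_titer"],
                nab_status=t["nab_status"],
                dilution=20.0,
            )
            rng = np.random.default_rng(children[idx])
            curves.append(
                simulate_curve(
                    scenario.dose_spec,
                    clones,
                    scenario.detection_scale,
                    scenario.noise,
                    sample_id=sample_id,
                    meta=meta,
                    rng=rng,
                )
            )
            truth.append({"sample_id": sample_id, "patient_id": plan.patient_id, **t})
            idx += 1
    return curves, truth


def truth_to_json(truth: list[dict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2)
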