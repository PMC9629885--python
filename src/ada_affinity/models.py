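"""Closed-form free-ADA response models for solution-equilibrium affinity curves.

A fixed amount of anti-drug antibody (ADA) is equilibrated against a serial
dilution of drug; the ADA still carrying at least one free paratope is then
detected in a bridging ligand-binding assay.  Under the excess-ligand
approximation (free drug ~ dosed drug), the expected signal for a single
affinity population is

    response(Dose) = Ab * (1 + 2*Dose*K_A) / (1 + Dose*K_A)**2
                   = Ab * (1 - 1 / (K_D/Dose + 1)**2),        K_A = 1/K_D,

where ``Ab`` is the maximal-phase signal (the zero-dose plateau) and ``K_D``
the per-site equilibrium dissociation constant.  The two printed forms are
algebraically identical; this module evaluates the ``K_A`` form, which is
finite at ``Dose = 0`` (the ``K_D`` form has a removable singularity there).
The biphasic model is the sum of two such terms, one per affinity
population, with the convention that phase 1 is the high-affinity
(smaller-``K_D``) phase.

All concentrations are carried internally in molar units; :func:`to_molar`
converts mass-per-volume drug doses using the drug's molar mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_MOLAR_MASS",
    "BindingParamsMono",
    "BindingParamsBi",
    "DoseSpec",
    "response_mono",
    "response_bi",
    "to_molar",
]

#: Nominal molar mass of a human IgG (g/mol), used to convert ng/mL drug
#: doses onto the molar scale of reported K_D values.  Overridable wherever
#: a dose conversion is performed.
DEFAULT_MOLAR_MASS = 150_000.0

# grams per litre for one unit of each supported mass-concentration unit
_MASS_UNITS = {
    "g/L": 1.0,
    "mg/mL": 1.0,
    "ug/mL": 1e-3,
    "µg/mL": 1e-3,
    "ng/mL": 1e-6,
    "pg/mL": 1e-9,
}
_MOLAR_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12, "fM": 1e-15}


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class BindingParamsMono:
    """Monophasic model parameters.

    Parameters
    ----------
    ab : float
        Maximum signal of the phase (zero-dose plateau), in assay signal units.
    kd : float
        Equilibrium dissociation constant, molar.
    """

    ab: float
    kd: float

    def __post_init__(self) -> None:
        _require_positive(ab=self.ab, kd=self.kd)


@dataclass(frozen=True)
class BindingParamsBi:
    """Biphasic model parameters, phase 1 being the high-affinity phase.

    Invariant: ``kd1 <= kd2`` (phase 1 = high affinity, phase 2 = low
    affinity).  All amplitudes and dissociation constants are positive.
    """

    ab1: float
    kd1: float
    ab2: float
    kd2: float

    def __post_init__(self) -> None:
        _require_positive(ab1=self.ab1, kd1=self.kd1, ab2=self.ab2, kd2=self.kd2)
        if self.kd1 > self.kd2:
            raise ValueError(f"kd1 must not exceed kd2 (got kd1={self.kd1!r}, kd2={self.kd2!r})")

    @property
    def kd_geo(self) -> float:
        """Geometric mean of the two dissociation constants."""
        return float(np.sqrt(self.kd1 * self.kd2))

    @property
    def proportion_high(self) -> float:
        """Fraction of total amplitude attributed to the high-affinity phase."""
        return self.ab1 / (self.ab1 + self.ab2)


@dataclass(frozen=True)
class DoseSpec:
    """A drug dose series with its unit provenance.

    ``doses`` are molar, in descending order as dispensed (top dose first).
    ``doses_source`` holds the same series in ``source_unit``.
    """

    doses: tuple[float, ...]
    source_unit: str = "M"
    molar_mass: float | None = None
    doses_source: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        arr = np.asarray(self.doses, dtype=float)
        if arr.size < 1 or not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("doses must be finite and non-negative")
        if not (np.all(np.diff(arr) <= 0) or np.all(np.diff(arr) >= 0)):
            raise ValueError("doses must be sorted")
        if self.source_unit in _MASS_UNITS and self.molar_mass is None:
            raise ValueError("molar_mass required for mass-concentration dose units")
        if not self.doses_source:
            object.__setattr__(self, "doses_source", self.doses)

    @property
    def doses_molar(self) -> np.ndarray:
        return np.asarray(self.doses, dtype=float)


def _check_dose(dose) -> np.ndarray:
    arr = np.asarray(dose, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("dose must be finite and non-negative")
    return arr


def response_mono(dose, params: BindingParamsMono):
    """Expected free-ADA signal for a single affinity population.

    Evaluates ``Ab*(1+2x)/(1+x)**2`` with ``x = dose/kd`` (the association-
    constant form, finite at zero dose, identical to the dissociation-
    constant form ``Ab*(1 - 1/(kd/dose + 1)**2)`` for ``dose > 0``).
    Equals ``Ab`` at zero dose, decreases strictly with dose, and tends to
    zero as the dose grows without bound.
    """
    arr = _check_dose(dose)
    x = arr / params.kd
    out = params.ab * (1.0 + 2.0 * x) / (1.0 + x) ** 2
    return out if out.ndim else float(out)


def response_bi(dose, params: BindingParamsBi):
    """Expected signal for two affinity populations: the sum of two
    monophasic terms, equal to ``ab1 + ab2`` at zero dose."""
    arr = _check_dose(dose)
    x1 = arr / params.kd1
    x2 = arr / params.kd2
    out = (
        params.ab1 * (1.0 + 2.0 * x1) / (1.0 + x1) ** 2
        + params.ab2 * (1.0 + 2.0 * x2) / (1.0 + x2) ** 2
    )
    return out if out.ndim else float(out)


def to_molar(value, unit: str, molar_mass: float | None = None):
    """Convert a concentration to molar.

    Mass-per-volume units (``ng/mL`` etc.) require ``molar_mass`` in g/mol;
    molar units are rescaled directly.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("concentration must be non-negative")
    if unit in _MOLAR_UNITS:
        out = arr * _MOLAR_UNITS[unit]
    elif unit in _MASS_UNITS:
        if molar_mass is None:
            raise ValueError(f"molar_mass required to convert {unit!r} to molar")
        _require_positive(molar_mass=molar_mass)
        out = arr * _MASS_UNITS[unit] / molar_mass
    else:
        raise ValueError(f"unknown concentration unit {unit!r}")
    return out if out.ndim else float(out)
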