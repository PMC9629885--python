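"""Run configuration: defaults, validation, and JSON/YAML loading."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .models import DEFAULT_MOLAR_MASS

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    """Tunable constants of the affinity workflow.

    Precedence when running the CLI: command-line flag > config file >
    these defaults.  The effective configuration is echoed into the output
    directory of every run.
    """

    drug_molar_mass: float = Field(DEFAULT_MOLAR_MASS, gt=0, description="g/mol")
    dose_unit: str = "ng/mL"
    flatness_level: float = Field(0.99, gt=0, lt=1)
    aic_probability_threshold: float = Field(0.5, ge=0.5, lt=1)
    recovery: float = Field(0.30, gt=0, le=1)
    signal_window_annotation: float = Field(4.0, gt=0)
    log_titer_annotation: float = Field(3.0)
    noise_cv: float = Field(0.08, ge=0)
    seed: int | None = None

    @field_validator("dose_unit")
    @classmethod
    def _known_unit(cls, v: str) -> str:
        from .models import _MASS_UNITS, _MOLAR_UNITS

        if v not in _MASS_UNITS and v not in _MOLAR_UNITS:
            raise ValueError(f"unknown dose unit {v!r}")
        return v

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("a seed is required for simulation commands")
        return self.seed


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a JSON or YAML config file and apply keyword overrides."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
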