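"""YAML run-configuration schema.

A run config has four blocks — instrument, sample, conditions, design —
plus a seed.  It is schema-validated (pydantic) before any computation;
violations surface as messages naming the offending field path.  Every
CLI run writes the resolved config next to its outputs.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import instrument as instr
from .samples import BUILTIN_SAMPLES, ParametricModel, get_sample


class ConfigError(ValueError):
    pass


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InstrumentConfig(_Block):
    band: tuple[float, float] = instr.DEFAULT_BAND
    theta_ref: float = Field(instr.DEFAULT_THETA_REF, gt=0)
    total_rate: float = Field(instr.DEFAULT_TOTAL_RATE, gt=0)
    n_bins: int = Field(100, ge=1)
    polarized: bool = False
    flux_file: Optional[str] = None

    def flux(self) -> instr.FluxProfile:
        if self.flux_file:
            return instr.load_flux(self.flux_file, theta_ref=self.theta_ref)
        return instr.synthesize_flux(
            band=self.band,
            total_rate=self.total_rate,
            polarized=self.polarized,
            n_bins=self.n_bins,
            theta_ref=self.theta_ref,
        )


class SampleConfig(_Block):
    builtin: str
    overrides: dict[str, float] = Field(default_factory=dict)

    def model(self) -> ParametricModel:
        if self.builtin not in BUILTIN_SAMPLES:
            raise ConfigError(
                f"sample.builtin: unknown sample {self.builtin!r}; "
                f"available: {sorted(BUILTIN_SAMPLES)}"
            )
        model = get_sample(self.builtin)
        for name, value in self.overrides.items():
            if any(p.name == name for p in model.parameters):
                model.param(name).value = value
            elif hasattr(model, name):
                setattr(model, name, value)
            else:
                raise ConfigError(f"sample.overrides.{name}: unknown attribute")
        return model


class ConditionsConfig(_Block):
    angles: list[float] = [0.7, 2.3]
    angle_fractions: list[float] = [0.2, 0.8]  # 15 min : 60 min
    total_time: float = Field(4500.0, gt=0)
    contrasts: list[Optional[float]] = [6.36, -0.56]
    contrast_fractions: Optional[list[float]] = None
    n_points: int = Field(100, ge=1)
    spins: list[Literal["unpolarized", "up", "down"]] = ["unpolarized"]


class DEConfig(_Block):
    strategy: str = "best1bin"
    popsize: int = Field(15, ge=4)
    tol: float = Field(0.01, gt=0)
    maxiter: int = Field(200, ge=1)
    polish: bool = True


class DesignConfig(_Block):
    optimize_what: Literal["contrasts", "angles", "underlayers"] = "contrasts"
    n_contrasts: int = Field(2, ge=1)
    n_angles: int = Field(2, ge=1)
    n_underlayers: int = Field(1, ge=0)
    de: DEConfig = DEConfig()


class RunConfig(_Block):
    seed: int = 0
    instrument: InstrumentConfig = InstrumentConfig()
    sample: SampleConfig
    conditions: ConditionsConfig = ConditionsConfig()
    design: DesignConfig = DesignConfig()


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; errors name the field path."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML ({exc})") from None
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        ]
        raise ConfigError(f"{path}: invalid config\n  " + "\n  ".join(lines)) from None


def config_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
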