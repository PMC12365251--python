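"""Validated pipeline configuration (YAML, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RatesBlock(_Strict):
    stomach_to_si: float = 0.8
    si_to_cecum: float = 0.75
    cecum_to_colon: float = 0.65
    colon_to_feces: float = 0.6

    @field_validator("*")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("transfer rates must be non-negative")
        return v


class ScenarioBlock(_Strict):
    daily_np_mass_mg: float = 3.3817
    daily_pd_mass_ug: float = 9.976
    schedule_h: list[float] = Field(default_factory=lambda: [0.0])
    gavage_volume_ul: float = 100.0
    rates: RatesBlock = Field(default_factory=RatesBlock)
    uptake_fraction: float = 0.01
    times_h: list[float] = Field(default_factory=lambda: [0.5, 1, 2, 4, 8, 12, 24])


class XfiBlock(_Strict):
    flux_ph_s: float = 5e11
    dwell_s: float = 1.0
    background_rate: float = 2.0
    reference_areal_masses_ug_cm2: list[float] = Field(default_factory=lambda: [5.0])
    grid_ny: int = 3
    grid_nx: int = 3


class IcpmsBlock(_Strict):
    slope: float = 5000.0
    intercept: float = 100.0
    blank_sd: float = 40.0
    drift: float = 0.05
    dilution_factor: float = 13.0 / 3.0
    digest_volume_ml: float = 3.0


class ImcBlock(_Strict):
    width: int = 40
    height: int = 40
    ions_per_particle: float = 1.0
    noise_max: float = 1.0
    particles_per_ug: float = 20.0
    max_particle_pixels: int = 60


class AnalysisBlock(_Strict):
    noise_ceiling: float = 1.0
    lod_factor: float = 3.0
    loq_factor: float = 10.0
    welch: bool = False


class PipelineConfig(_Strict):
    seed: int = 0
    scenario: ScenarioBlock = Field(default_factory=ScenarioBlock)
    xfi: XfiBlock = Field(default_factory=XfiBlock)
    icpms: IcpmsBlock = Field(default_factory=IcpmsBlock)
    imc: ImcBlock = Field(default_factory=ImcBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)


def load_config(path: Path) -> PipelineConfig:
    """Read and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return PipelineConfig.model_validate(raw)
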