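"""Validated pipeline configuration (pydantic models, unknown keys rejected)."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .synth.genotype import DEFAULT_EFFECTS, GenotypeEffect
from .synth.neuron import NeuronModelParams


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NeuronConfig(_Strict):
    capacitance: float = Field(30.0, gt=0)
    leak_conductance: float = Field(4.0, gt=0)
    leak_reversal: float = -65.0
    spike_threshold_slope_factor: float = Field(2.0, gt=0)
    intrinsic_threshold: float = -45.0
    reset_voltage: float = -55.0
    adaptation_increment: float = Field(40.0, ge=0)
    adaptation_time_constant: float = Field(120.0, gt=0)
    h_current_max_conductance: float = Field(2.0, ge=0)
    h_current_reversal: float = -30.0
    h_current_activation_midpoint: float = -85.0
    h_current_time_constant: float = Field(50.0, gt=0)
    h_current_activation_slope: float = Field(8.0, gt=0)
    noise_sd: float = Field(0.2, ge=0)

    def to_params(self) -> NeuronModelParams:
        return NeuronModelParams(**self.model_dump())


class EphysConfig(_Strict):
    sampling_rate_khz: float = Field(50.0, ge=10)
    n_cells_per_genotype: int = Field(4, ge=1)
    cell_param_cv: float = Field(0.1, ge=0)
    neuron: NeuronConfig = NeuronConfig()


class EpscConfig(_Strict):
    sampling_rate_khz: float = Field(10.0, ge=1)
    duration_s: float = Field(30.0, gt=0)
    rate_hz: float = Field(2.0, ge=0)
    amplitude_pa: float = Field(20.0, gt=0)
    rise_tau_ms: float = Field(1.0, gt=0)
    decay_tau_ms: float = Field(10.0, gt=0)
    noise_sd_pa: float = Field(4.0, ge=0)
    amplitude_cv: float = Field(0.3, ge=0)
    threshold_sds: float = Field(4.0, gt=0)


class CohortConfig(_Strict):
    n_animals: int = Field(8, ge=1)
    density_sd: float = Field(20.0, ge=0)
    cells_per_animal: int = Field(3000, ge=1)


class StatsConfig(_Strict):
    alpha: float = Field(0.05, gt=0, lt=1)


class PipelineConfig(_Strict):
    """Top-level configuration of the end-to-end synthetic study."""

    seed: int = 0
    genotypes: list[str] = ["WT", "cHet", "cKO"]
    genotype_multipliers: dict[str, dict[str, float]] | None = None
    ephys: EphysConfig = EphysConfig()
    epsc: EpscConfig = EpscConfig()
    cohort: CohortConfig = CohortConfig()
    stats: StatsConfig = StatsConfig()

    @field_validator("genotypes")
    @classmethod
    def _nonempty(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("at least one genotype required")
        return v

    def effects(self) -> dict[str, GenotypeEffect]:
        if self.genotype_multipliers is None:
            return {
                g: DEFAULT_EFFECTS.get(g, GenotypeEffect(g, {})) for g in self.genotypes
            }
        return {
            g: GenotypeEffect(g, self.genotype_multipliers.get(g, {}))
            for g in self.genotypes
        }


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a pipeline config from JSON or YAML (by extension); defaults if None."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig.model_validate(data or {})
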