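"""Run configuration: strict, schema-validated YAML.

A run configuration gathers everything a reproducible simulation
needs: the forcing scenario, the site grid, the species table, the
contaminant and selectivity constants, the simulation window and the
seed.  Unknown keys are rejected; defaults are filled in and the
load -> dump -> load round trip is idempotent.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .dynamics import ContaminantParams, PlanktonConfig
from .scenarios import ScenarioSpec, SecondPeak
from .species import default_species_table, load_species_table
from .trophic import SelectivityParams

__all__ = ["RunConfig", "load_config", "dump_config", "config_digest"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScenarioConfig(_Strict):
    start: str = "2002-01-01"
    end: str = "2013-02-28"
    accident_date: str = "2011-03-11"
    pre_range: tuple[float, float] = (1e-3, 3e-3)
    peak_max_Bq_l: float = 50.0
    peak_min_Bq_l: float = 0.5
    peak_center_lat: float = 37.42
    peak_width_deg: float = 0.45
    rise_d: int = 20
    decay_halflife_d: float = 25.0
    second_peak_amplitude: float = 0.5
    second_peak_lag_d: int = 40
    second_peak_rise_d: int = 10
    northern_second_peak: bool = True
    northern_lat: float = 38.0
    temp_mean_C: float = 17.5
    temp_amp_C: float = 7.5
    temp_phase_d: float = 135.0

    def base_spec(self, seed: int) -> ScenarioSpec:
        return ScenarioSpec(
            start=self.start,
            end=self.end,
            accident_date=self.accident_date,
            pre_range=tuple(self.pre_range),
            peak_Bq_l=self.peak_max_Bq_l,
            rise_d=self.rise_d,
            decay_halflife_d=self.decay_halflife_d,
            second_peak=None,
            temp_mean_C=self.temp_mean_C,
            temp_amp_C=self.temp_amp_C,
            temp_phase_d=self.temp_phase_d,
            seed=seed,
        )

    def second_peak(self) -> SecondPeak:
        return SecondPeak(
            amplitude=self.second_peak_amplitude,
            lag_d=self.second_peak_lag_d,
            rise_d=self.second_peak_rise_d,
        )


class GridConfig(_Strict):
    n_sites: int = 30
    lat_north: float = 38.5
    lat_south: float = 36.0
    longitude: float = 141.2
    high_resolution: bool = False


class ContaminantConfig(_Strict):
    mu: float = 7e-4
    AE: float = 0.75
    phys_halflife_yr: float = 30.07
    CR_phyto: float = 30.0
    CR_zoo: float = 40.0

    def params(self) -> ContaminantParams:
        return ContaminantParams(
            mu=self.mu,
            AE=self.AE,
            phys_halflife_yr=self.phys_halflife_yr,
            CR_phyto=self.CR_phyto,
            CR_zoo=self.CR_zoo,
        )


class SelectivityConfig(_Strict):
    rho1: float = 2.0
    beta1: float = 5.0
    rho2: float = 30.0
    beta2: float = 0.5

    def params(self) -> SelectivityParams:
        return SelectivityParams(self.rho1, self.beta1, self.rho2, self.beta2)


class PlanktonSection(_Strict):
    phyto_length_cm: float = 0.02
    zoo_length_cm: float = 0.245
    zoo_TL: float = 2.0
    n_bins: int = 4

    def params(self) -> PlanktonConfig:
        return PlanktonConfig(
            phyto_length_cm=self.phyto_length_cm,
            zoo_length_cm=self.zoo_length_cm,
            zoo_TL=self.zoo_TL,
            n_bins=self.n_bins,
        )


class RunConfig(_Strict):
    seed: int = 0
    species_table: str | None = None
    forcing_csv: str | None = None
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    contaminant: ContaminantConfig = Field(default_factory=ContaminantConfig)
    selectivity: SelectivityConfig = Field(default_factory=SelectivityConfig)
    plankton: PlanktonSection = Field(default_factory=PlanktonSection)

    @model_validator(mode="after")
    def _check(self):
        # fail early on an unusable species table (eta >= 1 etc.)
        self.species()
        return self

    def species(self):
        if self.species_table is None:
            return default_species_table()
        p = Path(self.species_table)
        if not p.exists():
            raise FileNotFoundError(f"species table not found: {p}")
        return load_species_table(p)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path=None) -> str:
    """Serialise a configuration back to YAML (round-trip stable)."""
    text = yaml.safe_dump(
        json.loads(config.model_dump_json()), sort_keys=True
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def config_digest(config: RunConfig) -> str:
    """Stable SHA-256 digest of the fully resolved configuration."""
    canonical = json.dumps(
        json.loads(config.model_dump_json()), sort_keys=True
    )
    return hashlib.sha256(canonical.encode("utf8")).hexdigest()
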