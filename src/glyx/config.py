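"""Validated run configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Dict, List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import electrokinetics as ek
from .errors import ConfigError
from .synthetic import StackSpec


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ElectrokineticsConfig(_Model):
    """Electrolyte and glycocalyx defaults (SI units)."""

    ionic_strength: float = 0.145
    temperature: float = 298.15
    viscosity: float = 8.9e-4
    relative_permittivity: float = 78.5
    thickness_beta: float = 7.8e-9
    segment_radius_a: float = 0.6e-9
    segment_surface_density: float = 1.4e17
    total_surface_charge: float = -0.0138
    membrane_surface_charge: float = 0.0
    cell_area: float = ek.RBC_AREA_DEFAULT
    outer_z_lo: float = ek.OUTER_Z_LO_DEFAULT
    graft_molar_mass: float = 20000.0
    hpg_radius_prefactor: float = 4.6e-11
    segments_per_molecule: float = 1.0
    n_nodes: int = 2000

    def electrolyte(self) -> ek.Electrolyte:
        return ek.Electrolyte(
            ionic_strength=self.ionic_strength,
            temperature=self.temperature,
            viscosity=self.viscosity,
            relative_permittivity=self.relative_permittivity)

    def glycocalyx(self) -> ek.GlycocalyxModel:
        return ek.GlycocalyxModel(
            thickness_beta=self.thickness_beta,
            segment_radius_a=self.segment_radius_a,
            segment_surface_density=self.segment_surface_density,
            total_surface_charge=self.total_surface_charge,
            membrane_surface_charge=self.membrane_surface_charge)

    def graft_radius(self) -> float:
        return ek.hpg_stokes_radius(self.graft_molar_mass,
                                    self.hpg_radius_prefactor)


class ChannelMapConfig(_Model):
    """Channel index per role for plain multichannel TIFFs."""

    membrane: int = 0
    probe: int = 1
    nuclei: Optional[int] = 2


class QuantConfig(_Model):
    k_sigma: float = 2.0
    signal_fraction: float = 0.5
    stat: Literal["median", "sum"] = "median"
    z_step_default: float = 0.2    # um


class DistributionConfig(_Model):
    """Crowded vs non-crowded grafting distribution experiment."""

    crowded_accessibility: float = 0.654   # accessible fraction under crowding


class CollapseConfig(_Model):
    """Crowder titration (doses in mg/mL, one compression per dose)."""

    doses: List[float] = [0.0, 57.5, 115.0, 230.0]
    compressions: List[float] = [1.0, 0.85, 0.7, 0.55]
    conserve_mass: bool = True
    washout: bool = True
    bleach_per_slice: float = 0.97


class MobilityConfig(_Model):
    molecules_grid: List[float] = [0.0, 2.0e5, 4.0e5, 6.0e5, 8.0e5,
                                   9.5e5, 1.2e6]
    scenario: Literal["uniform", "outer"] = "outer"
    noise_sd: float = 0.02
    free_params: List[str] = ["segment_surface_density"]


class CamouflageConfig(_Model):
    """True MFIs per antigen and condition for the cytometry generator."""

    truths: Dict[str, Dict[str, float]] = {
        "RhD": {"control": 1000.0, "noncrowded": 800.0, "crowded": 600.0},
        "CD47": {"control": 1200.0, "noncrowded": 1020.0, "crowded": 880.0},
    }
    cv: float = 0.1
    n_events: int = 10000
    n_replicates: int = 5


class RunConfig(_Model):
    """Top-level pipeline configuration."""

    experiment: Literal["distribution", "collapse", "camouflage", "mobility"]
    seed: int = 0
    outdir: str = "results"
    electrokinetics: ElectrokineticsConfig = ElectrokineticsConfig()
    channels: ChannelMapConfig = ChannelMapConfig()
    quant: QuantConfig = QuantConfig()
    stack: Dict = {}
    distribution: DistributionConfig = DistributionConfig()
    collapse: CollapseConfig = CollapseConfig()
    mobility: MobilityConfig = MobilityConfig()
    camouflage: CamouflageConfig = CamouflageConfig()

    def stack_spec(self, **overrides) -> StackSpec:
        merged = {**self.stack, **overrides}
        try:
            return StackSpec(**merged)
        except TypeError as exc:
            raise ConfigError(f"invalid stack spec: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(config: RunConfig) -> str:
    """Canonical YAML rendering of a resolved configuration."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Stable hash of the resolved configuration for provenance records."""
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:16]
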