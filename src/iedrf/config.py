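"""Run configuration: strict YAML schema and input resolution."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .environment import PolarizableEnvironment, read_environment
from .geometry import Molecule, read_xyz
from .scf import SCFOptions
from .units import angstrom_to_bohr


class DampingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    factor: float = Field(1.0, gt=0, description="r0 = factor * alpha^(1/3)")
    thole_a: float = Field(2.1304, gt=0)
    thole_damped: bool = True


class SCFConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_iterations: int = Field(200, ge=1)
    conv_energy: float = Field(1e-10, gt=0)
    conv_commutator: float = Field(1e-8, gt=0)
    diis: bool = True


class RunConfig(BaseModel):
    """Validated run description; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    qm_geometry: str                      # XYZ path (Angstrom)
    qm_charge: int = 0
    environment: str | None = None        # environment file path
    basis: str = "sto-3g"
    mode: str = Field("energy", pattern="^(energy|gradient|polarization-report)$")
    coarse_grain_cutoff: float | None = Field(
        None, gt=0, description="Angstrom; far molecules get one isotropic site")
    ri_mode: str = Field("exact-same-site", pattern="^(exact-same-site|pure-ri)$")
    damping: DampingConfig = DampingConfig()
    scf: SCFConfig = SCFConfig()
    seed: int = 0


#: default coarse-graining cutoff when enabled without a value (Angstrom)
DEFAULT_COARSE_GRAIN_CUTOFF = 5.0


@dataclass
class RunDescription:
    """Fully resolved inputs: internal units, exclusions and coarse-graining
    applied."""

    molecule: Molecule
    environment: PolarizableEnvironment
    options: SCFOptions
    mode: str
    seed: int
    config: RunConfig


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return RunConfig.model_validate(doc)


def resolve(config: RunConfig, base_dir: Path | None = None) -> RunDescription:
    base = Path(base_dir) if base_dir is not None else Path(".")
    mol = read_xyz(base / config.qm_geometry, charge=config.qm_charge)
    env = (read_environment(base / config.environment)
           if config.environment else PolarizableEnvironment())
    if config.coarse_grain_cutoff is not None and env.sites:
        from .polarization import coarse_grain
        env = coarse_grain(env, mol.coords,
                           angstrom_to_bohr(config.coarse_grain_cutoff),
                           thole_a=config.damping.thole_a,
                           damped=config.damping.thole_damped)
    options = SCFOptions(
        max_iterations=config.scf.max_iterations,
        conv_energy=config.scf.conv_energy,
        conv_commutator=config.scf.conv_commutator,
        diis=config.scf.diis,
        ri_mode=config.ri_mode,
        damping_factor=config.damping.factor,
        thole_a=config.damping.thole_a,
        thole_damped=config.damping.thole_damped,
    )
    return RunDescription(molecule=mol, environment=env, options=options,
                          mode=config.mode, seed=config.seed, config=config)


def parse_inputs(path) -> RunDescription:
    """Load, validate and resolve a run configuration file."""
    path = Path(path)
    return resolve(load_config(path), base_dir=path.parent)
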