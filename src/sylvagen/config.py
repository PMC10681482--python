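"""Structured run configuration, loadable from TOML.

A :class:`SimulationConfig` bundles the stand geometry, the genetic
architecture targets, the process parameters and the scenario plus the
three named random seeds (genetic setup, inventory, dynamics) that scope
the stochasticity of a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .core_state import InitialDiameterDistribution, Stand
from .growth import GrowthParams
from .mortality import DisturbanceRegime, SelfThinningParams
from .regeneration import DispersalKernel, FecundityParams
from .silviculture import Intervention, Scenario, scenario_library


@dataclass
class GeneticsConfig:
    """Targets for the founder-population genetic architecture."""

    variation: bool = True
    n_qtl: int = 50
    va_target: float = 0.0042    # cm^2/yr^2
    h2: float = 0.3
    ve_step: float = 0.0
    mean_target: float = 0.0
    tol_va: float = 0.02
    mean_tol_factor: float = 0.05
    kappa_contrib: float = 0.5
    kappa_freq: float = 2.0
    p_min: float = 0.05
    n_linkage_groups: int = 10
    max_iter: int = 1000


@dataclass
class SimulationConfig:
    stand: Stand = field(default_factory=Stand)
    initial_density: float = 2800.0     # stems/ha at age 25
    initial_age: int = 25
    reset_density: float = 2800.0       # density restored at recruitment
    diameters: InitialDiameterDistribution = field(
        default_factory=InitialDiameterDistribution)
    growth: GrowthParams = field(default_factory=GrowthParams)
    self_thinning: SelfThinningParams = field(
        default_factory=SelfThinningParams)
    disturbance: DisturbanceRegime = field(default_factory=DisturbanceRegime)
    fecundity: FecundityParams = field(default_factory=FecundityParams)
    kernel: DispersalKernel = field(default_factory=DispersalKernel)
    genetics: GeneticsConfig = field(default_factory=GeneticsConfig)
    scenario: Scenario = field(
        default_factory=lambda: scenario_library("U-long"))
    n_cycles: int = 4
    # optional starting inventory on disk; when unset the built-in
    # generator creates the initial condition
    inventory_file: Optional[str] = None
    haplotypes_file: Optional[str] = None
    qtl_map_file: Optional[str] = None
    setup_seed: int = 0
    inventory_seed: int = 1
    dynamics_seed: int = 2
    include_removals_in_production: bool = True
    h0_on_phenotype: bool = True
    # a seeding cut that cannot retain even this fraction of its seed-tree
    # target marks the run as a population collapse (0 keeps only the
    # strict no-fertile-tree criterion)
    collapse_seed_tree_fraction: float = 0.1

    def validate(self) -> None:
        problems = []
        if self.initial_density <= 0:
            problems.append("initial_density must be positive")
        if self.reset_density <= 0:
            problems.append("reset_density must be positive")
        if self.n_cycles < 1:
            problems.append("n_cycles must be >= 1")
        if self.initial_age < self.growth.recruitment_age:
            problems.append("initial_age must be >= recruitment age")
        first = min(iv.stand_age for iv in self.scenario.interventions)
        if first < self.initial_age:
            problems.append("interventions must not precede the initial age")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))


def _apply_section(obj, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(obj)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
    return dataclasses.replace(obj, **section)


def _scenario_from_section(section: dict) -> Scenario:
    if "name" in section and "interventions" not in section:
        return scenario_library(section["name"])
    ivs = tuple(
        Intervention(int(iv["stand_age"]), iv["kind"],
                     float(iv.get("target_density", 0.0)),
                     iv.get("mode", "random"))
        for iv in section["interventions"])
    return Scenario(section.get("name", "custom"), ivs)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a TOML configuration file.

    Recognized sections: [stand], [run], [genetics], [growth],
    [self_thinning], [disturbance], [fecundity], [dispersal], [diameters],
    [scenario], [rng].  Unknown keys are rejected with a message listing
    them.
    """
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = SimulationConfig()
    if "stand" in raw:
        cfg.stand = _apply_section(Stand(), raw["stand"], "stand")
    if "diameters" in raw:
        cfg.diameters = _apply_section(
            InitialDiameterDistribution(), raw["diameters"], "diameters")
    if "growth" in raw:
        cfg.growth = _apply_section(GrowthParams(), raw["growth"], "growth")
    if "self_thinning" in raw:
        cfg.self_thinning = _apply_section(
            SelfThinningParams(), raw["self_thinning"], "self_thinning")
    if "disturbance" in raw:
        cfg.disturbance = _apply_section(
            DisturbanceRegime(), raw["disturbance"], "disturbance")
    if "fecundity" in raw:
        cfg.fecundity = _apply_section(
            FecundityParams(), raw["fecundity"], "fecundity")
    if "dispersal" in raw:
        cfg.kernel = _apply_section(
            DispersalKernel(), raw["dispersal"], "dispersal")
    if "genetics" in raw:
        cfg.genetics = _apply_section(
            GeneticsConfig(), raw["genetics"], "genetics")
    if "scenario" in raw:
        cfg.scenario = _scenario_from_section(raw["scenario"])
    if "rng" in raw:
        for key in ("setup_seed", "inventory_seed", "dynamics_seed"):
            if key in raw["rng"]:
                setattr(cfg, key, int(raw["rng"][key]))
    if "run" in raw:
        for key in ("initial_density", "initial_age", "reset_density",
                    "n_cycles", "include_removals_in_production",
                    "h0_on_phenotype", "inventory_file", "haplotypes_file",
                    "qtl_map_file", "collapse_seed_tree_fraction"):
            if key in raw["run"]:
                setattr(cfg, key, raw["run"][key])
    cfg.validate()
    return cfg
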