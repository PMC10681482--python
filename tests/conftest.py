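"""Shared fixtures: small deterministic stands and run configurations."""

import dataclasses

import numpy as np
import pytest

import sylvagen as sg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_config(*, width=75.0, variation=True, scenario="U-long",
                 disturbance="none", setup_seed=0, inventory_seed=1,
                 dynamics_seed=2, n_cycles=4):
    """A compact stand (0.56 ha by default) with the standard process
    parameters, for pipeline-level tests."""
    cfg = sg.SimulationConfig()
    cfg.stand = sg.Stand(width_m=width, depth_m=width)
    # compact stands intercept a smaller share of the fat-tailed seed rain;
    # scale seedling numbers up so the recruitment reset stays saturated
    cfg.fecundity = dataclasses.replace(cfg.fecundity, seedling_multiplier=15.0)
    cfg.genetics.variation = variation
    cfg.scenario = sg.scenario_library(scenario)
    cfg.disturbance = sg.DisturbanceRegime(kind=disturbance)
    cfg.setup_seed = setup_seed
    cfg.inventory_seed = inventory_seed
    cfg.dynamics_seed = dynamics_seed
    cfg.n_cycles = n_cycles
    return cfg


@pytest.fixture(scope="session")
def shared_setup_50qtl():
    """One 50-QTL genetic setup sized for the 0.56 ha test stand, shared
    across tests to avoid re-running the optimizer."""
    n_founders = int(round(2800 * 0.5625))
    return sg.init_genetic_setup(50, 0.0042, n_founders,
                                 np.random.default_rng(0))
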