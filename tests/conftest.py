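"""Shared fixtures: coarse study valves and converged states.

Simulation-bearing fixtures are session-scoped: dynamic relaxation of a
full valve takes tens of seconds, so converged states are computed once
and shared. Mesh resolution is coarsened (2.5-3 mm edges) relative to the
generator default to keep the suite fast; the physics is unchanged.
"""

import numpy as np
import pytest

from mvteer.chordae import generate_chordae
from mvteer.geometry import SynthValveConfig, generate_synthetic_valve
from mvteer.material import FungParams
from mvteer.pipeline import DEFAULT_REGURGITANT
from mvteer.solver import SolverConfig, simulate_closure, simulate_opening

COARSE_EDGE = 2.5


@pytest.fixture(scope="session")
def healthy_config():
    return SynthValveConfig(mesh_edge_length=COARSE_EDGE, seed=0)


@pytest.fixture(scope="session")
def healthy_valve(healthy_config):
    return generate_synthetic_valve(healthy_config)


@pytest.fixture(scope="session")
def regurgitant_config():
    return SynthValveConfig.from_dict({**DEFAULT_REGURGITANT, "seed": 0})


@pytest.fixture(scope="session")
def regurgitant_valve(regurgitant_config):
    return generate_synthetic_valve(regurgitant_config)


@pytest.fixture(scope="session")
def fung_params():
    return FungParams()


@pytest.fixture(scope="session")
def solver_config():
    return SolverConfig()


@pytest.fixture(scope="session")
def healthy_chordae(healthy_valve):
    return generate_chordae(healthy_valve)


@pytest.fixture(scope="session")
def regurgitant_chordae(regurgitant_valve):
    return generate_chordae(regurgitant_valve)


@pytest.fixture(scope="session")
def healthy_closed(healthy_valve, healthy_chordae, fung_params, solver_config):
    return simulate_closure(healthy_valve, healthy_chordae, fung_params,
                            solver_config)


@pytest.fixture(scope="session")
def regurgitant_closed(regurgitant_valve, regurgitant_chordae, fung_params,
                       solver_config):
    return simulate_closure(regurgitant_valve, regurgitant_chordae, fung_params,
                            solver_config)


@pytest.fixture(scope="session")
def regurgitant_open(regurgitant_valve, regurgitant_chordae, fung_params,
                     solver_config):
    return simulate_opening(regurgitant_valve, regurgitant_chordae, fung_params,
                            solver_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
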