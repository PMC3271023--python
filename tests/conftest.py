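import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from gliomanet.network import (AngiogenesisParams, CellParams, Conversion,
                               CytokineParams, EdgeTarget, HillParams,
                               NetworkSpec, PathwayEdge, Producer, Species,
                               default_glioma_spec)
from gliomanet.dynamics import compile_model
from gliomanet.stochastic import default_jump_processes, default_noise_spec


@pytest.fixture(scope="session")
def spec():
    return default_glioma_spec()


@pytest.fixture(scope="session")
def model(spec):
    return compile_model(spec)


@pytest.fixture(scope="session")
def noise(spec):
    return default_noise_spec(spec)


@pytest.fixture(scope="session")
def jumps(spec):
    return default_jump_processes(spec)


def make_toy_spec(prolif=0.0, decay=0.0, secretion=5e-7, half_life=0.5,
                  edges=(), cbar=1e8, cell_init=1e5, cyt_init=0.0,
                  angio_gated=False, a_min=0.3, k_a=1.0):
    """One cell ('C') and one cytokine ('X') with configurable couplings."""
    species = [
        Species(id="C", name="cell", role="cell",
                initial_concentration=cell_init),
        Species(id="X", name="factor", role="cytokine",
                initial_concentration=cyt_init),
    ]
    cell_params = [CellParams("C", prolif, decay, cbar,
                              angiogenesis_gated=angio_gated)]
    cyt_params = [CytokineParams("X", [Producer("C", secretion)], half_life)]
    return NetworkSpec(
        name="toy", species=species, cell_params=cell_params,
        cytokine_params=cyt_params, edges=list(edges),
        angiogenesis=AngiogenesisParams(driver_cytokine_id="X", A_min=a_min,
                                        K_A=k_a, n_A=1.0),
    )


def toy_edge(eid, target_process, direction="up", a=2.0, K=1.0, n=1.0,
             species_id="C", cytokine_id=None, receptor=None):
    return PathwayEdge(
        id=eid, source_cytokine_id="X",
        target=EdgeTarget(species_id=species_id, process=target_process,
                          cytokine_id=cytokine_id),
        direction=direction, hill=HillParams(K=K, n=n, a=a),
        receptor_scale_param_id=receptor,
    )


@pytest.fixture
def toy_spec_factory():
    return make_toy_spec


@pytest.fixture
def toy_edge_factory():
    return toy_edge
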