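import numpy as np
import pytest

from ferrostress import (ParamSet, mesh_flow, mesh_tissue, solve_blood_flow)


@pytest.fixture(scope="session")
def p():
    return ParamSet()


@pytest.fixture(scope="session")
def tissue_mesh(p):
    """Coarse tissue mesh shared across tests."""
    return mesh_tissue(p, h_tumor=4e-4, h_far=1.2e-3)


@pytest.fixture(scope="session")
def flow_mesh(p):
    return mesh_flow(p, n_layers=4, h_arc=3e-4, h_axial=5e-4)


@pytest.fixture(scope="session")
def flow_no_force(p, flow_mesh):
    """Vessel flow without magnetic forcing."""
    return solve_blood_flow(flow_mesh, None, p)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240715)
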