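import numpy as np
import pytest

from fnstab.config_grid import standard_configuration
from fnstab.construct_mechanics import LoadCase
from fnstab.pipeline_audit import build_construct, solve_construct
from fnstab.synth_femur import SurrogateFemurSpec


@pytest.fixture(scope="session")
def coarse_spec():
    """Desk-scale surrogate: 5 mm linear tetrahedra."""
    return SurrogateFemurSpec(target_edge_length_mm=5.0, element_order=1, seed=11)


@pytest.fixture(scope="session")
def standard_construct(coarse_spec):
    """Standard-placement construct (mesh, hu, axis, plane), built once."""
    return build_construct(coarse_spec, standard_configuration())


@pytest.fixture(scope="session")
def standard_solution(standard_construct):
    """Solved standard construct under the default single-leg load."""
    mesh, hu, axis, plane = standard_construct
    load = LoadCase()
    sol, mats = solve_construct(mesh, hu, load=load)
    return mesh, load, sol, mats
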