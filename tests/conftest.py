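"""Shared fixtures: small meshes and pre-solved states reused across tests
to keep the suite inside a sensible wall-clock budget."""

import numpy as np
import pytest

from stomamech.geometry import GeometryParams, build_geometry
from stomamech.material import MaterialParams
from stomamech.solver import BCVariant, LoadProtocol, solve_quasistatic


@pytest.fixture(scope="session")
def small_params():
    return GeometryParams(mesh_resolution=600)


@pytest.fixture(scope="session")
def small_mesh(small_params):
    return build_geometry(small_params)


@pytest.fixture(scope="session")
def material():
    return MaterialParams()


@pytest.fixture(scope="session")
def short_protocol():
    return LoadProtocol(n_steps=12, p_gc_max=3.0)


@pytest.fixture(scope="session")
def baseline_small_states(small_mesh, material, short_protocol):
    """Baseline variant solved on the small mesh over a short ramp."""
    return solve_quasistatic(small_mesh, material, short_protocol,
                             BCVariant("baseline", "circular"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)
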