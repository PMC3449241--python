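import numpy as np
import pytest

import hexstim as hs
from hexstim.fem import solve_montage


@pytest.fixture(scope="session")
def coarse_phantom():
    """Default layered phantom at 4 mm (fast enough for many unit tests)."""
    return hs.generate_sphere_phantom(resolution=4.0)


@pytest.fixture(scope="session")
def coarse_solved():
    """A fully solved coarse (4 mm) FPz-Oz problem shared across tests."""
    vol = hs.generate_sphere_phantom(resolution=4.0)
    montage = hs.standard_montage("FPz-Oz")
    vol = hs.place_electrode_patches(vol, montage)
    mesh = hs.voxels_to_hex_mesh(vol)
    mesh = hs.geometry_adapt(mesh, vol, 0.33)
    mesh = hs.assign_conductivity(mesh)
    solution = solve_montage(mesh, montage)
    return vol, mesh, montage, solution


@pytest.fixture(scope="session")
def three_layer_solution():
    """Solved three-layer validation sphere at 4 mm (coarse but fast)."""
    from hexstim.fem import solve_montage as _solve
    from hexstim.validation import build_three_layer_problem

    mesh, montage, model = build_three_layer_problem(resolution_mm=4.0)
    solution = _solve(mesh, montage)
    return mesh, montage, model, solution


@pytest.fixture()
def bar_mesh():
    """1x1xN single-tissue bar with 1 mm voxels (Ohm's-law geometry)."""
    n = 10
    labels = np.full((1, 1, n), hs.Tissue.SKIN, dtype=np.int16)
    vol = hs.LabelVolume(labels, 1.0, np.zeros(3))
    mesh = hs.voxels_to_hex_mesh(vol)
    return hs.assign_conductivity(mesh), vol
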