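"""Stiffness assembly, Neumann loads, CG solve, current density."""

import numpy as np
import pytest

import hexstim as hs
from hexstim.fem import (
    AssemblyError,
    LinearSystem,
    LoadError,
    assemble_stiffness,
    compute_current_density,
    electrode_load_vector,
    solve_montage,
    solve_potential,
    surface_flux,
)
from hexstim.meshing import voxels_to_hex_mesh
from hexstim.phantom import LabelVolume, Tissue


def brute_force_unit_cube_stiffness():
    """Independent 2x2x2 quadrature of int grad(Ni).grad(Nj) dV on [0,1]^3.

    Shape functions and quadrature coded from first principles with plain
    loops, independent of the vectorized assembly path.
    """
    signs = [
        (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
        (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
    ]

    def grad(a, xi):
        sx, sy, sz = signs[a]
        return np.array(
            [
                sx * (1 + sy * xi[1]) * (1 + sz * xi[2]) / 8,
                sy * (1 + sx * xi[0]) * (1 + sz * xi[2]) / 8,
                sz * (1 + sx * xi[0]) * (1 + sy * xi[1]) / 8,
            ]
        )

    g = 1 / np.sqrt(3)
    k = np.zeros((8, 8))
    for gx in (-g, g):
        for gy in (-g, g):
            for gz in (-g, g):
                xi = (gx, gy, gz)
                # unit cube: x = (xi+1)/2 -> d(xi)/dx = 2, detJ = 1/8
                for i in range(8):
                    for j in range(8):
                        k[i, j] += (2 * grad(i, xi)) @ (2 * grad(j, xi)) / 8
    return k


def single_cube_mesh(sigma=1.0):
    labels = np.full((1, 1, 1), Tissue.SKIN, dtype=np.int16)
    mesh = voxels_to_hex_mesh(LabelVolume(labels, 1000.0, np.zeros(3)))  # 1 m cube
    return hs.assign_conductivity(mesh, {Tissue.SKIN: sigma})


class TestAssembleStiffness:
    def test_unit_cube_matches_brute_force_quadrature(self):
        mesh = single_cube_mesh()
        k = assemble_stiffness(mesh).toarray()
        e = mesh.elements[0]  # map element-vertex convention -> node numbering
        assert np.allclose(k[np.ix_(e, e)], brute_force_unit_cube_stiffness(), atol=1e-13)

    def test_row_sums_zero(self, coarse_solved):
        _, mesh, _, _ = coarse_solved
        k = assemble_stiffness(mesh)
        assert np.abs(k @ np.ones(mesh.n_nodes)).max() < 1e-10

    def test_symmetry(self):
        k = assemble_stiffness(single_cube_mesh(0.43))
        assert (abs(k - k.T)).max() < 1e-15

    def test_rank_deficiency_is_exactly_one(self):
        labels = np.full((2, 1, 1), Tissue.GM, dtype=np.int16)
        mesh = hs.assign_conductivity(
            voxels_to_hex_mesh(LabelVolume(labels, 1.0, np.zeros(3)))
        )
        k = assemble_stiffness(mesh).toarray()
        assert np.linalg.matrix_rank(k, tol=1e-12) == mesh.n_nodes - 1

    def test_unassigned_tensors_rejected(self):
        labels = np.full((1, 1, 1), Tissue.SKIN, dtype=np.int16)
        mesh = voxels_to_hex_mesh(LabelVolume(labels, 1.0, np.zeros(3)))
        with pytest.raises(AssemblyError):
            assemble_stiffness(mesh)


class TestElectrodeLoad:
    def test_polarity_sums_and_compatibility(self, coarse_solved):
        _, mesh, montage, _ = coarse_solved
        b = electrode_load_vector(mesh, montage)
        assert b[b > 0].sum() == pytest.approx(montage.total_current, rel=1e-12)
        assert b[b < 0].sum() == pytest.approx(-montage.total_current, rel=1e-12)
        assert abs(b.sum()) < 1e-12 * montage.total_current

    def test_nodal_weights_proportional_to_face_areas(self, coarse_solved):
        """Each exposed face carries current I * area / total_area, split
        over its 4 nodes — verified by an independent face-area summation."""
        from hexstim.fem import _patch_outer_faces
        from hexstim.meshing import quad_areas_normals

        _, mesh, montage, _ = coarse_solved
        b = electrode_load_vector(mesh, montage)
        face_nodes, areas = _patch_outer_faces(mesh, Tissue.ELECTRODE_ANODE)
        expected = np.zeros(mesh.n_nodes)
        total_area = 0.0
        for fn in face_nodes:
            p = mesh.nodes[fn]
            a = np.linalg.norm(np.cross(p[2] - p[0], p[3] - p[1])) / 2
            total_area += a
        for fn in face_nodes:
            p = mesh.nodes[fn]
            a = np.linalg.norm(np.cross(p[2] - p[0], p[3] - p[1])) / 2
            for node in fn:
                expected[node] += montage.total_current * a / total_area / 4
        anode_nodes = expected > 0
        assert np.allclose(b[anode_nodes], expected[anode_nodes], rtol=1e-9)

    def test_missing_electrode_rejected(self, coarse_phantom):
        mesh = hs.assign_conductivity(voxels_to_hex_mesh(coarse_phantom))
        with pytest.raises(LoadError):
            electrode_load_vector(mesh, hs.standard_montage("FPz-Oz"))


class TestSolvePotential:
    def test_zero_load_gives_zero_potential(self, coarse_solved):
        _, mesh, _, _ = coarse_solved
        k = assemble_stiffness(mesh)
        phi, info = solve_potential(LinearSystem(k, np.zeros(mesh.n_nodes)), mesh=mesh)
        assert (phi == 0).all()
        assert info.iterations == 0

    def test_incompatible_load_rejected(self, coarse_solved):
        _, mesh, _, _ = coarse_solved
        k = assemble_stiffness(mesh)
        bad = np.zeros(mesh.n_nodes)
        bad[0] = 1e-3  # pure source, no sink
        with pytest.raises(LoadError):
            solve_potential(LinearSystem(k, bad), mesh=mesh)

    def test_zero_mean_gauge(self, coarse_solved):
        _, _, _, solution = coarse_solved
        assert abs(solution.potential.mean()) < 1e-12 * np.abs(solution.potential).max()

    def test_ohms_law_bar(self, bar_mesh):
        """End-to-end potential difference on a 1x1xN bar equals I L / (sigma A):
        trilinear elements reproduce the linear field exactly."""
        mesh, _ = bar_mesh
        n_nodes = mesh.n_nodes
        z = mesh.nodes[:, 2]
        top = np.isclose(z, z.max())
        bottom = np.isclose(z, z.min())
        current = 1.0e-3
        b = np.zeros(n_nodes)
        b[top] = current / top.sum()
        b[bottom] = -current / bottom.sum()
        k = assemble_stiffness(mesh)
        phi, _ = solve_potential(
            LinearSystem(k, b), rel_tol=1e-13, mesh=mesh, preconditioner="jacobi"
        )
        sigma, area, length = 0.43, 1.0e-6, (z.max() - z.min())
        expected = current * length / (sigma * area)
        measured = phi[top].mean() - phi[bottom].mean()
        assert measured == pytest.approx(expected, rel=1e-8)

    def test_jacobi_and_amg_agree(self, coarse_solved):
        _, mesh, montage, solution = coarse_solved
        alt = solve_montage(mesh, montage, preconditioner="jacobi")
        scale = np.abs(solution.potential).max()
        assert np.abs(alt.potential - solution.potential).max() < 1e-6 * scale


class TestCurrentDensity:
    def test_constant_potential_gives_zero_j(self, coarse_solved):
        _, mesh, _, _ = coarse_solved
        j = compute_current_density(mesh, np.full(mesh.n_nodes, 3.14))
        # zero up to rounding in the shape-gradient partition of unity
        assert np.abs(j).max() < 1e-9

    def test_linear_potential_reproduced_exactly(self):
        labels = np.full((3, 2, 2), Tissue.CSF, dtype=np.int16)
        mesh = hs.assign_conductivity(voxels_to_hex_mesh(LabelVolume(labels, 1.0, np.zeros(3))))
        g = 2.5  # V/m along x
        phi = g * mesh.nodes[:, 0]
        j = compute_current_density(mesh, phi)
        expected = np.array([-1.79 * g, 0.0, 0.0])
        assert np.allclose(j, expected[None, :], atol=1e-12)

    def test_polarity_swap_negates_j_exactly(self, coarse_solved):
        _, mesh, montage, solution = coarse_solved
        k = assemble_stiffness(mesh)
        b = electrode_load_vector(mesh, montage)
        phi_neg, _ = solve_potential(LinearSystem(k, -b), mesh=mesh)
        j_neg = compute_current_density(mesh, phi_neg)
        assert (phi_neg == -solution.potential).all()
        assert (j_neg == -solution.current_density).all()

    def test_linearity_in_total_current(self, coarse_solved):
        _, mesh, montage, solution = coarse_solved
        doubled = solve_montage(mesh, montage.with_current(2.0e-3))
        assert np.allclose(
            doubled.current_density, 2.0 * solution.current_density, rtol=1e-12, atol=0
        )


class TestConservation:
    def test_flux_through_separating_plane(self, coarse_solved):
        """Net discrete flux of J across a closed voxel-aligned surface
        separating anode from cathode recovers the injected current."""
        _, mesh, montage, solution = coarse_solved
        cent = mesh.element_centroids() - mesh.center_m
        inside = cent[:, 1] > 0  # anode (FPz, +y) side
        flux = surface_flux(mesh, solution.current_density, inside)
        assert flux == pytest.approx(montage.total_current, rel=0.02)


def test_point_reflection_antisymmetry():
    """Homogeneous sphere with antipodal patches: Phi(-x) = -Phi(x) up to
    solver tolerance (the mesh lattice is symmetric under point reflection)."""
    layer = ((Tissue.SKIN, 40.0),)
    vol = hs.generate_sphere_phantom(layer_spec=layer, resolution=4.0, margin_mm=6.0)
    montage = hs.Montage(
        patches=[
            hs.ElectrodePatch((90.0, 0.0), "anode", width_mm=16, height_mm=16),
            hs.ElectrodePatch((90.0, 180.0), "cathode", width_mm=16, height_mm=16),
        ]
    )
    vol = hs.place_electrode_patches(vol, montage)
    mesh = hs.assign_conductivity(voxels_to_hex_mesh(vol))
    rel_tol = 1e-9
    # Jacobi preconditioning commutes with the reflection, so CG iterates
    # stay antisymmetric to rounding rather than just to residual level.
    solution = solve_montage(mesh, montage, rel_tol=rel_tol, preconditioner="jacobi")
    key = np.round(mesh.nodes * 1e6).astype(np.int64)
    index = {tuple(k): i for i, k in enumerate(key)}
    partner = np.array([index[tuple(-k)] for k in key])
    asym = np.abs(solution.potential + solution.potential[partner]).max()
    assert asym <= 10 * rel_tol * np.abs(solution.potential).max() + 1e-15
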