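"""Quasistatic finite-element forward problem.

In the quasistatic approximation of Maxwell's equations, the potential in a
volume conductor solves div(sigma grad Phi) = 0 with inhomogeneous Neumann
boundary conditions: a prescribed normal current density on the exposed
electrode surfaces (total +I at the anode, -I at the cathode) and zero flux
elsewhere.  Discretization uses isoparametric trilinear hexahedra with 2x2x2
Gauss quadrature and a constant conductivity tensor per element, giving a
sparse symmetric positive-semidefinite system with the constant vector in its
null space.  The system is solved with multigrid-preconditioned conjugate
gradients and gauged to a zero-mean potential; the current density is then
J = -sigma grad Phi at each element centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix

from ._amg import SmoothedAggregationPreconditioner
from .meshing import (
    FACE_VERTICES,
    HexMesh,
    _shape_gradients_ref,
    gauss_points,
    neighbor_table,
    quad_areas_normals,
)
from .phantom import Montage, Tissue

__all__ = [
    "LinearSystem",
    "SolverInfo",
    "StimulationSolution",
    "assemble_stiffness",
    "electrode_load_vector",
    "solve_potential",
    "compute_current_density",
    "solve_montage",
    "surface_flux",
]


class AssemblyError(RuntimeError):
    pass


class LoadError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass
class LinearSystem:
    """Sparse stiffness matrix plus nodal current loads (amperes)."""

    stiffness: csr_matrix
    load: np.ndarray


@dataclass
class SolverInfo:
    iterations: int
    relative_residual: float
    n_unknowns: int
    preconditioner: str = "amg"


@dataclass
class StimulationSolution:
    """Nodal potential (V, zero-mean gauge) and element current density (A/m^2)."""

    potential: np.ndarray
    current_density: np.ndarray
    solver_info: SolverInfo

    def scaled(self, factor: float) -> "StimulationSolution":
        return StimulationSolution(
            self.potential * factor, self.current_density * factor, self.solver_info
        )


def assemble_stiffness(mesh: HexMesh) -> csr_matrix:
    """Stiffness matrix K_ij = sum_e int grad(N_i) . sigma grad(N_j) dV.

    2x2x2 Gauss quadrature on trilinear shape functions — exact for trilinear
    geometry with a constant tensor per element.  Assembly order is element-
    index order, so repeated runs are bit-identical.
    """
    if mesh.element_tensor is None:
        raise AssemblyError("mesh has no conductivity tensors; run assign_conductivity first")
    coords = mesh.element_coords()  # (E, 8, 3)
    sigma = mesh.element_tensor
    n_el = mesh.n_elements
    ke = np.zeros((n_el, 8, 8))
    for xi in gauss_points():
        g = _shape_gradients_ref(xi)  # (8, 3)
        jac = np.einsum("eac,ad->ecd", coords, g)  # (E, 3, 3)
        det = np.linalg.det(jac)
        if (det <= 0).any():
            raise AssemblyError("non-positive Jacobian encountered during assembly")
        jinv = np.linalg.inv(jac)
        gphys = np.einsum("ad,edc->eac", g, jinv)  # (E, 8, 3) physical gradients
        flux = np.einsum("ecd,ejd->ejc", sigma, gphys)
        ke += np.einsum("eac,ejc->eaj", gphys, flux) * det[:, None, None]

    rows = np.repeat(mesh.elements, 8, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 8)).ravel()
    k = coo_matrix((ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes))
    return k.tocsr()


def _patch_outer_faces(mesh: HexMesh, code: int, min_radial_cos: float = 0.25):
    """Exposed outer faces of an electrode patch.

    Exterior faces of patch elements whose outward normal points away from
    the head center (cosine above ``min_radial_cos``), i.e. the free saline
    surface where the stimulator injects current — not the skin interface.
    """
    nb = neighbor_table(mesh)
    sel = mesh.element_label == code
    ext = (nb < 0) & sel[:, None]
    elem_idx, face_dir = np.nonzero(ext)
    if len(elem_idx) == 0:
        return None
    face_nodes = mesh.elements[elem_idx[:, None], FACE_VERTICES[face_dir]]
    areas, normals = quad_areas_normals(mesh.nodes, face_nodes)
    centers = mesh.nodes[face_nodes].mean(axis=1)
    radial = centers - mesh.center_m
    radial /= np.maximum(np.linalg.norm(radial, axis=1), 1e-300)[:, None]
    outer = np.einsum("fc,fc->f", normals, radial) > min_radial_cos
    if not outer.any():
        return None
    return face_nodes[outer], areas[outer]


def electrode_exposed_area(mesh: HexMesh, code: int, projected: bool = True) -> float:
    """Area (m^2) of an electrode's exposed outer surface.

    With ``projected=True`` the staircase faces are projected onto the local
    radial direction, which recovers the geodesic footprint area of the
    patch; the raw face-area sum overestimates it (staircase inflation).
    """
    faces = _patch_outer_faces(mesh, code)
    if faces is None:
        raise LoadError(f"electrode {code} has no exposed outer face")
    face_nodes, areas = faces
    if not projected:
        return float(areas.sum())
    _, normals = quad_areas_normals(mesh.nodes, face_nodes)
    centers = mesh.nodes[face_nodes].mean(axis=1) - mesh.center_m
    rhat = centers / np.maximum(np.linalg.norm(centers, axis=1), 1e-300)[:, None]
    return float((areas * np.einsum("fc,fc->f", normals, rhat)).sum())


def electrode_load_vector(mesh: HexMesh, montage: Montage) -> np.ndarray:
    """Nodal current loads from a uniform normal current density per polarity.

    Each exposed outer electrode face carries the same normal current
    density; a face's current is split equally among its four nodes.  Anode
    loads sum to ``+total_current``, cathode loads to ``-total_current``.
    """
    load = np.zeros(mesh.n_nodes)
    for code, sign in ((Tissue.ELECTRODE_ANODE, +1.0), (Tissue.ELECTRODE_CATHODE, -1.0)):
        if not (mesh.element_label == code).any():
            raise LoadError(f"mesh has no elements with electrode code {code}")
        faces = _patch_outer_faces(mesh, code)
        if faces is None:
            raise LoadError(f"electrode {code} has no exposed outer face")
        face_nodes, areas = faces
        face_current = areas / areas.sum() * montage.total_current * sign
        contrib = np.zeros(mesh.n_nodes)
        for corner in range(4):
            np.add.at(contrib, face_nodes[:, corner], face_current / 4.0)
        load += contrib
    return load


def solve_potential(
    system: LinearSystem,
    rel_tol: float = 1e-9,
    max_iter: int = 10000,
    mesh: HexMesh | None = None,
    preconditioner: str = "amg",
) -> tuple[np.ndarray, SolverInfo]:
    """Preconditioned CG for the singular-but-consistent Neumann system.

    The load must sum to zero (charge conservation); the returned potential is
    projected to zero mean.  Convergence is declared at
    ``||K x - b|| <= rel_tol * ||b||``.
    """
    k = system.stiffness
    b = np.asarray(system.load, dtype=float)
    bnorm = np.linalg.norm(b)
    n = k.shape[0]
    if bnorm == 0:
        return np.zeros(n), SolverInfo(0, 0.0, n, preconditioner)
    if abs(b.sum()) > 1e-10 * np.abs(b).sum():
        raise LoadError(f"load vector is incompatible: sums to {b.sum():.3e} A")

    if preconditioner == "amg":
        if mesh is None or mesh.voxel_size_mm is None:
            raise AssemblyError("amg preconditioner needs the mesh geometry")
        prec = SmoothedAggregationPreconditioner(
            k, mesh.nodes, mesh.voxel_size_mm / 1000.0
        )
        apply_m = prec.matvec
    elif preconditioner == "jacobi":
        d = k.diagonal()
        dinv = 1.0 / np.maximum(d, 1e-300)
        apply_m = lambda r: dinv * r  # noqa: E731
    else:
        raise ValueError(f"unknown preconditioner {preconditioner!r}")

    # PCG, keeping iterates orthogonal to the constant null vector
    x = np.zeros(n)
    r = b.copy()
    z = apply_m(r)
    z -= z.mean()
    p = z.copy()
    rz = r @ z
    history = [1.0]
    for it in range(1, max_iter + 1):
        kp = k @ p
        alpha = rz / (p @ kp)
        x += alpha * p
        r -= alpha * kp
        relres = np.linalg.norm(r) / bnorm
        history.append(float(relres))
        if relres <= rel_tol:
            x -= x.mean()
            return x, SolverInfo(it, float(relres), n, preconditioner)
        z = apply_m(r)
        z -= z.mean()
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise ConvergenceError(
        f"CG did not reach rel_tol={rel_tol:g} in {max_iter} iterations "
        f"(final {history[-1]:.3e})",
        history,
    )


def compute_current_density(mesh: HexMesh, potential: np.ndarray) -> np.ndarray:
    """Per-element J = -sigma grad(Phi) at the element centroid (A/m^2).

    Sign convention: physical current flows from anode to cathode (the
    potential gradient points uphill, the current downhill).
    """
    if mesh.element_tensor is None:
        raise AssemblyError("mesh has no conductivity tensors")
    if len(potential) != mesh.n_nodes:
        raise ValueError("potential length does not match node count")
    coords = mesh.element_coords()
    g = _shape_gradients_ref(np.zeros(3))  # centroid
    jac = np.einsum("eac,ad->ecd", coords, g)
    jinv = np.linalg.inv(jac)
    gphys = np.einsum("ad,edc->eac", g, jinv)  # (E, 8, 3)
    phi_e = potential[mesh.elements]  # (E, 8)
    grad_phi = np.einsum("ea,eac->ec", phi_e, gphys)
    return -np.einsum("ecd,ed->ec", mesh.element_tensor, grad_phi)


def solve_montage(
    mesh: HexMesh,
    montage: Montage,
    rel_tol: float = 1e-9,
    max_iter: int = 10000,
    preconditioner: str = "amg",
) -> StimulationSolution:
    """Assemble, solve, and differentiate in one call."""
    system = LinearSystem(assemble_stiffness(mesh), electrode_load_vector(mesh, montage))
    phi, info = solve_potential(
        system, rel_tol=rel_tol, max_iter=max_iter, mesh=mesh, preconditioner=preconditioner
    )
    j = compute_current_density(mesh, phi)
    return StimulationSolution(phi, j, info)


def surface_flux(
    mesh: HexMesh, current_density: np.ndarray, inside: np.ndarray
) -> float:
    """Net current (A) crossing the closed surface around ``inside`` elements.

    The surface is the set of element faces separating ``inside`` from
    outside elements; J on a face is the average of the two adjacent element
    values, and orientation is inside -> outside.  Exterior faces carry the
    prescribed boundary flux and are not part of the inter-element surface.
    """
    inside = np.asarray(inside, dtype=bool)
    nb = neighbor_table(mesh)
    total = 0.0
    for d in range(6):
        n_d = nb[:, d]
        valid = n_d >= 0
        crossing = valid & inside & ~inside[np.maximum(n_d, 0)]
        if not crossing.any():
            continue
        e_in = np.nonzero(crossing)[0]
        face_nodes = mesh.elements[e_in[:, None], FACE_VERTICES[np.full(len(e_in), d)]]
        areas, normals = quad_areas_normals(mesh.nodes, face_nodes)
        j_avg = 0.5 * (current_density[e_in] + current_density[n_d[e_in]])
        total += float(np.einsum("f,fc,fc->", areas, j_avg, normals))
    return total
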