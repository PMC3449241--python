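"""Geometry-adapted hexahedral meshing of label volumes.

One trilinear hexahedral element per non-background voxel, with nodes shared
between adjacent voxels.  A single smoothing pass then shifts nodes that lie
on material interfaces (or on the outer boundary) toward the centroid of the
surrounding interface-face centers, clamped to ``shift_factor`` voxel sizes,
which softens the voxel staircase while keeping all isoparametric Jacobians
positive.

Vertex ordering convention (trilinear hexahedron): bottom face counter-
clockwise viewed from +z, then the top face in the same order::

    0:(0,0,0) 1:(1,0,0) 2:(1,1,0) 3:(0,1,0)
    4:(0,0,1) 5:(1,0,1) 6:(1,1,1) 7:(0,1,1)

Node coordinates are stored in meters; the label grid is in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .phantom import LabelVolume, Tissue

__all__ = [
    "HexMesh",
    "voxels_to_hex_mesh",
    "geometry_adapt",
    "jacobian_determinants",
    "element_volumes",
    "exterior_faces",
    "neighbor_table",
    "save_mesh",
    "load_mesh",
    "export_vtk",
    "MM_PER_M",
]

MM_PER_M = 1000.0

#: Local vertex offsets (i, j, k) in the fixed ordering convention.
VERTEX_OFFSETS = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=np.int64,
)

#: Element faces by local vertex ids, keyed by the +-axis direction they face.
#: Order: (-x, +x, -y, +y, -z, +z); vertices are listed so that the
#: right-hand-rule normal points out of the element.
FACE_VERTICES = np.array(
    [
        [0, 4, 7, 3],  # -x
        [1, 2, 6, 5],  # +x
        [0, 1, 5, 4],  # -y
        [3, 7, 6, 2],  # +y
        [0, 3, 2, 1],  # -z
        [4, 5, 6, 7],  # +z
    ],
    dtype=np.int64,
)

#: Axis step for each face direction, matching FACE_VERTICES rows.
FACE_STEPS = np.array(
    [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]], dtype=np.int64
)

_GAUSS_1D = np.array([-1.0, 1.0]) / np.sqrt(3.0)


class MeshError(RuntimeError):
    pass


class MeshAdaptationError(MeshError):
    pass


@dataclass
class HexMesh:
    """Hexahedral mesh with per-element tissue label and conductivity tensor.

    ``element_tensor`` is ``None`` until conductivities are assigned.
    ``voxel_ijk`` maps each element back to its source voxel, which the
    pipeline uses for tensor lookup and for resampling fields onto the grid.
    """

    nodes: np.ndarray  # (N, 3) float64, meters
    elements: np.ndarray  # (E, 8) int64
    element_label: np.ndarray  # (E,) int16
    element_tensor: np.ndarray | None = None  # (E, 3, 3) S/m
    voxel_ijk: np.ndarray | None = None  # (E, 3) int32
    grid_shape: tuple[int, int, int] | None = None
    voxel_size_mm: float | None = None
    origin_mm: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def has_tensors(self) -> bool:
        return self.element_tensor is not None

    @property
    def center_m(self) -> np.ndarray:
        """Physical center of the source voxel grid, in meters."""
        if self.origin_mm is not None and self.grid_shape is not None:
            c = self.origin_mm + (np.array(self.grid_shape) - 1) / 2.0 * self.voxel_size_mm
            return c / MM_PER_M
        return self.nodes.mean(axis=0)

    def element_coords(self) -> np.ndarray:
        """(E, 8, 3) node coordinates per element."""
        return self.nodes[self.elements]

    def element_centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def copy(self) -> "HexMesh":
        return HexMesh(
            self.nodes.copy(),
            self.elements.copy(),
            self.element_label.copy(),
            None if self.element_tensor is None else self.element_tensor.copy(),
            None if self.voxel_ijk is None else self.voxel_ijk.copy(),
            self.grid_shape,
            self.voxel_size_mm,
            None if self.origin_mm is None else self.origin_mm.copy(),
        )


def voxels_to_hex_mesh(vol: LabelVolume) -> HexMesh:
    """One hexahedral element per non-background voxel, shared nodes.

    Element order follows C-order voxel scanning, and node numbering follows
    the sorted corner-lattice index, so repeated runs are bit-identical.
    """
    sel = vol.labels != Tissue.BACKGROUND
    if not sel.any():
        raise MeshError("label volume contains no non-background voxels")
    ijk = np.argwhere(sel).astype(np.int64)  # C order == np.flatnonzero order
    nx, ny, nz = vol.labels.shape
    corner_dims = (nx + 1, ny + 1, nz + 1)

    corners = ijk[:, None, :] + VERTEX_OFFSETS[None, :, :]  # (E, 8, 3)
    keys = np.ravel_multi_index(
        (corners[..., 0], corners[..., 1], corners[..., 2]), corner_dims
    )
    unique_keys, inverse = np.unique(keys.ravel(), return_inverse=True)
    elements = inverse.reshape(-1, 8).astype(np.int64)

    ci, cj, ck = np.unravel_index(unique_keys, corner_dims)
    h = vol.voxel_size
    nodes = np.stack(
        [
            vol.origin[0] + (ci - 0.5) * h,
            vol.origin[1] + (cj - 0.5) * h,
            vol.origin[2] + (ck - 0.5) * h,
        ],
        axis=1,
    ) / MM_PER_M

    return HexMesh(
        nodes=nodes,
        elements=elements,
        element_label=vol.labels[sel].astype(np.int16),
        voxel_ijk=ijk.astype(np.int32),
        grid_shape=vol.labels.shape,
        voxel_size_mm=vol.voxel_size,
        origin_mm=np.asarray(vol.origin, dtype=float),
    )


def neighbor_table(mesh: HexMesh) -> np.ndarray:
    """(E, 6) element index of the neighbor across each face direction
    (-x, +x, -y, +y, -z, +z), or -1 where the face is exterior."""
    if mesh.voxel_ijk is None or mesh.grid_shape is None:
        raise MeshError("mesh lacks voxel bookkeeping; was it built by voxels_to_hex_mesh?")
    shape = mesh.grid_shape
    lookup = np.full(int(np.prod(shape)), -1, dtype=np.int64)
    flat = np.ravel_multi_index(tuple(mesh.voxel_ijk.T), shape)
    lookup[flat] = np.arange(mesh.n_elements)

    out = np.full((mesh.n_elements, 6), -1, dtype=np.int64)
    for d in range(6):
        nb = mesh.voxel_ijk.astype(np.int64) + FACE_STEPS[d]
        ok = ((nb >= 0) & (nb < np.array(shape))).all(axis=1)
        flat_nb = np.ravel_multi_index(tuple(nb[ok].T), shape)
        out[ok, d] = lookup[flat_nb]
    return out


def exterior_faces(mesh: HexMesh, element_mask: np.ndarray | None = None):
    """Exterior faces (no neighbor element) of the selected elements.

    Returns ``(elem_idx, face_dir, face_nodes)`` where ``face_nodes`` is
    (F, 4) global node ids in outward orientation.
    """
    nb = neighbor_table(mesh)
    ext = nb < 0
    if element_mask is not None:
        ext &= element_mask[:, None]
    elem_idx, face_dir = np.nonzero(ext)
    face_nodes = mesh.elements[elem_idx[:, None], FACE_VERTICES[face_dir]]
    return elem_idx, face_dir, face_nodes


def quad_areas_normals(nodes: np.ndarray, face_nodes: np.ndarray):
    """Area and unit normal of (possibly mildly warped) quad faces.

    Uses the cross product of the diagonals: exact for planar quads and a
    standard area measure for bilinear ones.
    """
    p = nodes[face_nodes]  # (F, 4, 3)
    d1 = p[:, 2] - p[:, 0]
    d2 = p[:, 3] - p[:, 1]
    cr = np.cross(d1, d2)
    area2 = np.linalg.norm(cr, axis=1)
    normals = np.divide(cr, np.maximum(area2, 1e-300)[:, None])
    return area2 / 2.0, normals


def _shape_gradients_ref(xi: np.ndarray) -> np.ndarray:
    """(8, 3) gradients of the trilinear shape functions at reference point xi."""
    signs = VERTEX_OFFSETS * 2 - 1  # (+-1, +-1, +-1)
    g = np.empty((8, 3))
    for a in range(8):
        s = signs[a]
        g[a, 0] = s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2]) / 8.0
        g[a, 1] = s[1] * (1 + s[0] * xi[0]) * (1 + s[2] * xi[2]) / 8.0
        g[a, 2] = s[2] * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) / 8.0
    return g


def gauss_points() -> np.ndarray:
    """The 2x2x2 Gauss points in the reference cube (weights are all 1)."""
    pts = np.array(
        [[gx, gy, gz] for gx in _GAUSS_1D for gy in _GAUSS_1D for gz in _GAUSS_1D]
    )
    return pts


def jacobian_determinants(mesh: HexMesh) -> np.ndarray:
    """(E, 8) isoparametric Jacobian determinant at every Gauss point."""
    coords = mesh.element_coords()  # (E, 8, 3)
    dets = np.empty((mesh.n_elements, 8))
    for q, xi in enumerate(gauss_points()):
        G = _shape_gradients_ref(xi)  # (8, 3)
        J = np.einsum("eac,ad->ecd", coords, G)  # (E, 3, 3) dX/dxi
        dets[:, q] = np.linalg.det(J)
    return dets


def element_volumes(mesh: HexMesh) -> np.ndarray:
    """Element volumes in m^3 by 2x2x2 Gauss quadrature (unit weights)."""
    return jacobian_determinants(mesh).sum(axis=1)


def is_connected(mesh: HexMesh) -> bool:
    e = mesh.elements
    rows = np.concatenate([e[:, [0, 1, 2, 3, 4, 5, 6, 0]].ravel()])
    cols = np.concatenate([e[:, [1, 2, 3, 0, 5, 6, 7, 4]].ravel()])
    g = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    n_comp, _ = connected_components(g, directed=False)
    return n_comp == 1


def geometry_adapt(mesh: HexMesh, vol: LabelVolume, shift_factor: float = 0.33) -> HexMesh:
    """Shift interface and boundary nodes toward smoothed material interfaces.

    A node's target is the centroid of the centers of its incident interface
    faces (faces between differing labels, or exterior faces); displacement is
    clamped per component to ``shift_factor`` voxel sizes.  Interior nodes do
    not move.  Raises :class:`MeshAdaptationError` if any element's Jacobian
    becomes non-positive.
    """
    if not (0.0 <= shift_factor <= 0.49):
        raise MeshError("shift_factor must lie in [0, 0.49]")
    nb = neighbor_table(mesh)
    labels = mesh.element_label

    # interface faces: exterior, or neighbor with a different label.  Count
    # each geometric face once (owner = lower element index or exterior face).
    face_elem: list[np.ndarray] = []
    face_dir: list[np.ndarray] = []
    for d in range(6):
        n_d = nb[:, d]
        ext = n_d < 0
        diff = ~ext & (labels[np.maximum(n_d, 0)] != labels)
        own = ext | (diff & (n_d > np.arange(mesh.n_elements)))
        idx = np.nonzero(own)[0]
        face_elem.append(idx)
        face_dir.append(np.full(len(idx), d))
    face_elem = np.concatenate(face_elem)
    face_dir = np.concatenate(face_dir)
    face_nodes = mesh.elements[face_elem[:, None], FACE_VERTICES[face_dir]]  # (F, 4)
    face_centers = mesh.nodes[face_nodes].mean(axis=1)  # (F, 3)

    acc = np.zeros_like(mesh.nodes)
    cnt = np.zeros(mesh.n_nodes)
    for corner in range(4):
        np.add.at(acc, face_nodes[:, corner], face_centers)
        np.add.at(cnt, face_nodes[:, corner], 1.0)

    moving = cnt > 0
    target = np.where(moving[:, None], acc / np.maximum(cnt, 1)[:, None], mesh.nodes)
    delta = target - mesh.nodes
    cap = shift_factor * vol.voxel_size / MM_PER_M
    delta = np.clip(delta, -cap, cap)
    delta[~moving] = 0.0

    out = mesh.copy()
    out.nodes = mesh.nodes + delta
    dets = jacobian_determinants(out)
    bad = np.nonzero((dets <= 0).any(axis=1))[0]
    if len(bad):
        raise MeshAdaptationError(
            f"adaptation produced non-positive Jacobians in elements {bad[:10].tolist()}"
        )
    return out


# ---------------------------------------------------------------------------
# persistence

def save_mesh(mesh: HexMesh, path) -> None:
    """Persist the mesh in a flat HDF5 layout (nodes/elements/labels/tensors)."""
    with h5py.File(str(path), "w") as f:
        f.attrs["vertex_ordering"] = "bottom face CCW (0..3), then top face (4..7)"
        f.attrs["units"] = "meters; tensors S/m"
        f.create_dataset("nodes", data=mesh.nodes)
        f.create_dataset("elements", data=mesh.elements)
        f.create_dataset("labels", data=mesh.element_label)
        if mesh.element_tensor is not None:
            f.create_dataset("tensors", data=mesh.element_tensor)
        if mesh.voxel_ijk is not None:
            f.create_dataset("voxel_ijk", data=mesh.voxel_ijk)
            f.attrs["grid_shape"] = mesh.grid_shape
            f.attrs["voxel_size_mm"] = mesh.voxel_size_mm
            f.attrs["origin_mm"] = mesh.origin_mm


def load_mesh(path) -> HexMesh:
    with h5py.File(str(path), "r") as f:
        mesh = HexMesh(
            nodes=f["nodes"][()],
            elements=f["elements"][()],
            element_label=f["labels"][()],
            element_tensor=f["tensors"][()] if "tensors" in f else None,
            voxel_ijk=f["voxel_ijk"][()] if "voxel_ijk" in f else None,
            grid_shape=tuple(f.attrs["grid_shape"]) if "grid_shape" in f.attrs else None,
            voxel_size_mm=float(f.attrs["voxel_size_mm"]) if "voxel_size_mm" in f.attrs else None,
            origin_mm=np.asarray(f.attrs["origin_mm"]) if "origin_mm" in f.attrs else None,
        )
    return mesh


def export_vtk(mesh: HexMesh, path, cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK unstructured-grid export for external viewers."""
    with open(str(path), "w") as f:
        f.write("# vtk DataFile Version 3.0\nhexstim mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.9g")
        f.write(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}\n")
        cells = np.column_stack([np.full(mesh.n_elements, 8), mesh.elements])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(f, np.full(mesh.n_elements, 12), fmt="%d")  # VTK_HEXAHEDRON
        data = {"tissue": mesh.element_label}
        if cell_data:
            data.update(cell_data)
        f.write(f"CELL_DATA {mesh.n_elements}\n")
        for name, values in data.items():
            values = np.asarray(values)
            if values.ndim == 1:
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, values, fmt="%.9g")
            else:
                f.write(f"VECTORS {name} double\n")
                np.savetxt(f, values, fmt="%.9g")
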