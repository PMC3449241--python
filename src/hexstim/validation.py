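"""Solver validation against the analytic layered-sphere series.

A three-layer isotropic sphere (brain / skull / scalp, the classic
three-shell volume-conductor model: 0.33 / 0.0042 / 0.33 S/m at radii
78 / 84 / 90 mm) is voxelized, meshed and solved with small saline patches
(2 cm x 2 cm) standing in for point electrodes at antipodal scalp positions.
The FE potential is then compared with the zonal-harmonic series on a
mid-brain shell, excluding polar caps around the electrodes where the
point/patch discrepancy dominates.
"""

from __future__ import annotations

import numpy as np

from .conductivity import TissueTable, assign_conductivity
from .fem import solve_montage
from .meshing import geometry_adapt, voxels_to_hex_mesh
from .oracle import OracleReport, SphereModel, compare_to_oracle
from .phantom import (
    ElectrodePatch,
    Montage,
    Tissue,
    direction_from_angles,
    generate_sphere_phantom,
    place_electrode_patches,
)

__all__ = ["THREE_LAYER_SPEC", "THREE_LAYER_SIGMA", "build_three_layer_problem", "three_layer_validation"]

#: Brain / skull / scalp shells (tissue code, outer radius mm).
THREE_LAYER_SPEC = (
    (Tissue.GM, 78.0),
    (Tissue.SKULL_COMPACTA, 84.0),
    (Tissue.SKIN, 90.0),
)

#: Classic three-shell conductivities, S/m.
THREE_LAYER_SIGMA = {
    Tissue.GM: 0.33,
    Tissue.SKULL_COMPACTA: 0.0042,
    Tissue.SKIN: 0.33,
}

#: Antipodal electrode positions (inclination, azimuth) in degrees.
_SOURCE_ANGLES = (90.0, 0.0)
_SINK_ANGLES = (90.0, 180.0)


def small_patch_montage(
    patch_mm: float = 20.0, total_current: float = 1.0e-3
) -> Montage:
    return Montage(
        patches=[
            ElectrodePatch(_SOURCE_ANGLES, "anode", width_mm=patch_mm, height_mm=patch_mm),
            ElectrodePatch(_SINK_ANGLES, "cathode", width_mm=patch_mm, height_mm=patch_mm),
        ],
        total_current=total_current,
        name="validation",
    )


def build_three_layer_problem(
    resolution_mm: float = 2.0,
    patch_mm: float = 20.0,
    shift_factor: float = 0.33,
    total_current: float = 1.0e-3,
):
    """Voxelize, mesh and conductivity-tag the three-layer sphere.

    Returns ``(mesh, montage, model)`` with the analytic :class:`SphereModel`
    matching the phantom's layers.
    """
    vol = generate_sphere_phantom(layer_spec=THREE_LAYER_SPEC, resolution=resolution_mm)
    montage = small_patch_montage(patch_mm, total_current)
    vol = place_electrode_patches(vol, montage)
    mesh = voxels_to_hex_mesh(vol)
    if shift_factor > 0:
        mesh = geometry_adapt(mesh, vol, shift_factor)
    mesh = assign_conductivity(mesh, TissueTable(THREE_LAYER_SIGMA))
    model = SphereModel(
        layer_radii=np.array([r for _, r in THREE_LAYER_SPEC]) / 1000.0,
        layer_conductivities=np.array([THREE_LAYER_SIGMA[c] for c, _ in THREE_LAYER_SPEC]),
        source_dir=direction_from_angles(*_SOURCE_ANGLES),
        sink_dir=direction_from_angles(*_SINK_ANGLES),
        total_current=total_current,
    )
    return mesh, montage, model


def three_layer_validation(
    resolution_mm: float = 2.0,
    n_terms: int = 200,
    rel_tol: float = 1e-9,
    patch_mm: float = 20.0,
    shift_factor: float = 0.33,
    preconditioner: str = "amg",
) -> OracleReport:
    """End-to-end FE-versus-series error report on the three-layer sphere."""
    mesh, montage, model = build_three_layer_problem(
        resolution_mm=resolution_mm, patch_mm=patch_mm, shift_factor=shift_factor
    )
    solution = solve_montage(mesh, montage, rel_tol=rel_tol, preconditioner=preconditioner)
    report = compare_to_oracle(solution, mesh, model, n_terms=n_terms)
    report.details["resolution_mm"] = resolution_mm
    report.details["n_elements"] = mesh.n_elements
    report.details["iterations"] = solution.solver_info.iterations
    return report
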