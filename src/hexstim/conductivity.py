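"""Tissue conductivity assignment.

Isotropic compartments receive literature conductivities; white matter can
instead carry conductivity tensors derived from a diffusion-like tensor field
by the effective-medium approach: the conductivity tensor shares the
diffusion tensor's eigenvectors, and its eigenvalues are rescaled by one
positive factor so the geometric mean equals the tissue's isotropic target
(volume constraint).  This preserves the anisotropy ratio exactly and makes
``det(sigma)^(1/3)`` equal the target in every element.
"""

from __future__ import annotations

import numpy as np

from .meshing import HexMesh
from .phantom import TensorField, Tissue

__all__ = [
    "TissueTable",
    "DEFAULT_CONDUCTIVITIES",
    "assign_conductivity",
    "effective_medium_scale",
]

#: Default isotropic conductivities in S/m.
DEFAULT_CONDUCTIVITIES: dict[int, float] = {
    Tissue.SKIN: 0.43,
    Tissue.SKULL_COMPACTA: 0.007,
    Tissue.SKULL_SPONGIOSA: 0.025,
    Tissue.CSF: 1.79,
    Tissue.GM: 0.24,
    Tissue.WM: 0.19,
    Tissue.ELECTRODE_ANODE: 1.4,  # saline-soaked sponge
    Tissue.ELECTRODE_CATHODE: 1.4,
}


class ConductivityError(ValueError):
    pass


class TissueTable(dict):
    """Tissue code -> isotropic conductivity (S/m); defaults can be overridden.

    >>> TissueTable({Tissue.SKIN: 0.5})[Tissue.SKIN]
    0.5
    """

    def __init__(self, overrides: dict[int, float] | None = None):
        super().__init__(DEFAULT_CONDUCTIVITIES)
        if overrides:
            self.update(overrides)
        for code, sigma in self.items():
            if sigma <= 0:
                raise ConductivityError(f"conductivity for tissue {code} must be > 0, got {sigma}")


def effective_medium_scale(tensor: np.ndarray, sigma_iso_target: float) -> np.ndarray:
    """Rescale SPD diffusion-like tensor(s) to conductivity tensor(s).

    The output is ``s * tensor`` with the scalar ``s`` chosen so that the
    geometric mean of the output eigenvalues — ``det(sigma)^(1/3)`` — equals
    ``sigma_iso_target``.  Eigenvectors and eigenvalue ratios are untouched.
    Accepts a single (3, 3) tensor or a stack (..., 3, 3).
    """
    if sigma_iso_target <= 0:
        raise ConductivityError("sigma_iso_target must be > 0")
    t = np.asarray(tensor, dtype=float)
    single = t.ndim == 2
    if single:
        t = t[None]
    if np.abs(t - np.transpose(t, (0, 2, 1))).max() > 1e-10 * max(np.abs(t).max(), 1e-300):
        raise ConductivityError("tensor is not symmetric")
    det = np.linalg.det(t)
    if (det <= 0).any() or (np.linalg.eigvalsh(t) <= 0).any():
        raise ConductivityError("tensor is not positive definite")
    scale = sigma_iso_target / np.cbrt(det)
    out = t * scale[:, None, None]
    return out[0] if single else out


def assign_conductivity(
    mesh: HexMesh,
    table: TissueTable | dict[int, float] | None = None,
    tensors: TensorField | None = None,
    anisotropic_tissues: tuple[int, ...] = (Tissue.WM,),
) -> HexMesh:
    """Attach a 3x3 conductivity tensor to every element (returns a new mesh).

    Elements of isotropic tissues get ``sigma * I``.  Elements of
    ``anisotropic_tissues`` with a defined voxel tensor get the
    effective-medium-scaled tensor targeted at that tissue's table value;
    such elements *must* have a defined tensor when ``tensors`` is given.
    """
    if table is None:
        table = TissueTable()
    labels = np.unique(mesh.element_label)
    missing = [int(l) for l in labels if int(l) not in table]
    if missing:
        raise ConductivityError(f"tissue codes {missing} missing from the conductivity table")

    sigma_iso = np.array([table[int(l)] for l in mesh.element_label])
    tensor = np.eye(3)[None, :, :] * sigma_iso[:, None, None]

    if tensors is not None:
        if mesh.voxel_ijk is None or mesh.grid_shape is None:
            raise ConductivityError("mesh lacks voxel bookkeeping needed for tensor lookup")
        for code in anisotropic_tissues:
            sel = mesh.element_label == code
            if not sel.any():
                continue
            flat = np.ravel_multi_index(tuple(mesh.voxel_ijk[sel].T), mesh.grid_shape)
            try:
                d_tensors = tensors.lookup(flat)
            except KeyError:
                raise ConductivityError(
                    f"tissue {code} elements without a defined diffusion tensor"
                ) from None
            tensor[sel] = effective_medium_scale(d_tensors, table[int(code)])

    eigvals = np.linalg.eigvalsh(tensor)
    if (eigvals <= 0).any():
        raise ConductivityError("assigned conductivity tensors are not all SPD")

    out = mesh.copy()
    out.element_tensor = tensor
    return out
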