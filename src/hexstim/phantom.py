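"""Synthetic layered-sphere head phantoms.

The phantom stands in for a segmented MRI head model: six nested tissue
compartments (skin, skull compacta, skull spongiosa, CSF, gray matter, white
matter) voxelized on a regular grid, with optional gyral gray-matter ridges
protruding into the CSF shell and an optional white-matter anisotropy tensor
field.  Electrode patches are placed as saline-filled slabs on the scalp at
10-20-analog angular positions.

Angular convention (right-handed, head-centered):

* ``+z`` — vertex (Cz), inclination 0 deg,
* ``+y`` — nasion direction, azimuth 0 deg,
* ``+x`` — subject's right; azimuth increases toward the right.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "Tissue",
    "LabelVolume",
    "TensorField",
    "ElectrodePatch",
    "Montage",
    "GyrusSpec",
    "DEFAULT_LAYERS",
    "generate_sphere_phantom",
    "generate_wm_tensor_field",
    "place_electrode_patches",
    "ten_twenty_direction",
    "standard_montage",
    "direction_from_angles",
    "save_label_volume",
    "load_label_volume",
]


class Tissue:
    """Integer tissue codes used throughout the package (stable file contract)."""

    BACKGROUND = 0
    SKIN = 1
    SKULL_COMPACTA = 2
    SKULL_SPONGIOSA = 3
    CSF = 4
    GM = 5
    WM = 6
    ELECTRODE_ANODE = 7
    ELECTRODE_CATHODE = 8

    ALL = (0, 1, 2, 3, 4, 5, 6, 7, 8)
    BRAIN = (CSF, GM, WM)
    ELECTRODES = (ELECTRODE_ANODE, ELECTRODE_CATHODE)


#: Default nested-shell specification, innermost first: ``(tissue code, outer
#: radius in mm)``.  Approximates an adult head; the skull is a
#: compacta/spongiosa/compacta sandwich.
DEFAULT_LAYERS: tuple[tuple[int, float], ...] = (
    (Tissue.WM, 64.0),
    (Tissue.GM, 71.0),
    (Tissue.CSF, 74.0),
    (Tissue.SKULL_COMPACTA, 76.0),
    (Tissue.SKULL_SPONGIOSA, 79.0),
    (Tissue.SKULL_COMPACTA, 81.0),
    (Tissue.SKIN, 86.0),
)


class PhantomSpecificationError(ValueError):
    """Raised for invalid phantom / montage specifications."""


@dataclass
class LabelVolume:
    """Voxelized tissue segmentation on a regular grid.

    Attributes
    ----------
    labels : ndarray of int16, shape ``dims``
        Tissue code per voxel (see :class:`Tissue`).
    voxel_size : float
        Isotropic edge length of a voxel in mm.
    origin : ndarray shape (3,)
        Physical coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    labels: np.ndarray
    voxel_size: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 3:
            raise PhantomSpecificationError("labels must be a 3-D array")
        if self.voxel_size <= 0:
            raise PhantomSpecificationError("voxel_size must be > 0")
        if not np.isin(np.unique(self.labels), Tissue.ALL).all():
            raise PhantomSpecificationError("labels contain codes outside the tissue enumeration")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def center(self) -> np.ndarray:
        """Physical center of the grid in mm."""
        return self.origin + (np.array(self.dims) - 1) / 2.0 * self.voxel_size

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical voxel-center coordinates (mm)."""
        return tuple(
            self.origin[a] + np.arange(self.dims[a]) * self.voxel_size for a in range(3)
        )

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.labels.copy(), self.voxel_size, self.origin.copy())

    def count(self, code: int) -> int:
        return int(np.count_nonzero(self.labels == code))


@dataclass
class TensorField:
    """Per-voxel symmetric positive-definite 3x3 tensors on a sparse support.

    ``tensors[i]`` belongs to the voxel ``np.flatnonzero(defined_mask)[i]``
    (C order), mirroring how diffusion tensors exist only where DTI was
    acquired and registered.
    """

    defined_mask: np.ndarray  # bool, same shape as the label grid
    tensors: np.ndarray  # (n_defined, 3, 3)

    def __post_init__(self) -> None:
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
        self.tensors = np.asarray(self.tensors, dtype=float)
        n = int(self.defined_mask.sum())
        if self.tensors.shape != (n, 3, 3):
            raise PhantomSpecificationError(
                f"tensors shape {self.tensors.shape} does not match {n} defined voxels"
            )

    def is_spd(self, tol: float = 0.0) -> bool:
        if len(self.tensors) == 0:
            return True
        sym = np.abs(self.tensors - np.transpose(self.tensors, (0, 2, 1))).max()
        if sym > 1e-12:
            return False
        eigvals = np.linalg.eigvalsh(self.tensors)
        return bool((eigvals > tol).all())

    def lookup(self, flat_voxel_indices: np.ndarray) -> np.ndarray:
        """Tensors for the given flat voxel indices (C order); raises KeyError
        if any requested voxel has no defined tensor."""
        defined_flat = np.flatnonzero(self.defined_mask.ravel())
        if len(defined_flat) == 0:
            raise KeyError("tensor field has no defined voxels")
        pos = np.searchsorted(defined_flat, flat_voxel_indices)
        pos = np.clip(pos, 0, len(defined_flat) - 1)
        ok = defined_flat[pos] == flat_voxel_indices
        if not ok.all():
            raise KeyError("tensor requested for voxels outside the defined mask")
        return self.tensors[pos]


@dataclass(frozen=True)
class ElectrodePatch:
    """A rectangular saline electrode patch on the scalp.

    ``position`` is (inclination from vertex, azimuth from nasion) in degrees;
    the long axis (``width_mm``) runs along the local azimuthal direction.
    """

    position: tuple[float, float]
    polarity: str  # "anode" | "cathode"
    width_mm: float = 70.0
    height_mm: float = 50.0
    thickness_mm: float = 4.0
    conductivity: float = 1.4

    def __post_init__(self) -> None:
        if self.polarity not in ("anode", "cathode"):
            raise PhantomSpecificationError(f"invalid polarity {self.polarity!r}")
        if min(self.width_mm, self.height_mm, self.thickness_mm) <= 0:
            raise PhantomSpecificationError("patch dimensions must be positive")

    @property
    def code(self) -> int:
        return Tissue.ELECTRODE_ANODE if self.polarity == "anode" else Tissue.ELECTRODE_CATHODE


@dataclass
class Montage:
    """Electrode configuration: patches plus the total injected current (A)."""

    patches: list[ElectrodePatch] = field(default_factory=list)
    total_current: float = 1.0e-3
    name: str = ""

    def __post_init__(self) -> None:
        if self.total_current <= 0:
            raise PhantomSpecificationError("total_current must be > 0")
        if self.patches:
            polarities = {p.polarity for p in self.patches}
            if polarities != {"anode", "cathode"}:
                raise PhantomSpecificationError("montage needs at least one anode and one cathode")

    def with_current(self, total_current: float) -> "Montage":
        return replace(self, total_current=total_current)


@dataclass(frozen=True)
class GyrusSpec:
    """Radial gray-matter ridges that replace CSF in angular sectors.

    ``count`` ridges are centered at azimuths ``k * 360/count + offset``, each
    spanning ``width_deg`` of azimuth and the inclination band
    ``incl_range_deg``, over the full thickness of the CSF shell — a schematic
    stand-in for gyri protruding into CSF.
    """

    count: int = 8
    width_deg: float = 10.0
    incl_range_deg: tuple[float, float] = (30.0, 150.0)
    offset_deg: float = 0.0


# ---------------------------------------------------------------------------
# angular helpers

def direction_from_angles(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector for (inclination from vertex, azimuth from nasion) degrees."""
    th = np.deg2rad(inclination_deg)
    ph = np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)])


def angles_from_direction(v: np.ndarray) -> tuple[float, float]:
    v = np.asarray(v, float)
    v = v / np.linalg.norm(v)
    incl = np.rad2deg(np.arccos(np.clip(v[2], -1, 1)))
    az = np.rad2deg(np.arctan2(v[0], v[1]))
    return float(incl), float(az)


#: 10-20-analog angular coordinates, derived by equal-arc spacing of the
#: standard outer 10% ring (inclination 90 deg) with the vertex at Cz.
_TEN_TWENTY: dict[str, tuple[float, float]] = {
    "Cz": (0.0, 0.0),
    "FPz": (90.0, 0.0),
    "Oz": (90.0, 180.0),
    "F7": (90.0, -54.0),
    "F8": (90.0, 54.0),
    "P7": (90.0, -126.0),
    "P8": (90.0, 126.0),
}


def ten_twenty_direction(label: str) -> tuple[float, float]:
    """(inclination, azimuth) in degrees of a supported 10-20 position."""
    try:
        return _TEN_TWENTY[label]
    except KeyError:
        raise KeyError(
            f"unknown 10-20 label {label!r}; supported: {sorted(_TEN_TWENTY)}"
        ) from None


def standard_montage(name: str, total_current: float = 1.0e-3, **patch_kwargs) -> Montage:
    """Two-patch montage named ``"<anode>-<cathode>"``, e.g. ``"FPz-Oz"``."""
    try:
        anode_label, cathode_label = name.split("-")
    except ValueError:
        raise PhantomSpecificationError(
            f"montage name {name!r} must look like 'FPz-Oz'"
        ) from None
    return Montage(
        patches=[
            ElectrodePatch(ten_twenty_direction(anode_label), "anode", **patch_kwargs),
            ElectrodePatch(ten_twenty_direction(cathode_label), "cathode", **patch_kwargs),
        ],
        total_current=total_current,
        name=name,
    )


# ---------------------------------------------------------------------------
# phantom generation

def generate_sphere_phantom(
    layer_spec: tuple[tuple[int, float], ...] | None = None,
    resolution: float = 2.0,
    gyrus_spec: GyrusSpec | None = None,
    margin_mm: float | None = None,
) -> LabelVolume:
    """Voxelize nested concentric tissue shells into a :class:`LabelVolume`.

    Each voxel is labeled by the innermost layer whose outer radius is >= the
    distance of the voxel center from the phantom center.  The grid is even-
    sized and centered on the phantom, so the voxel lattice is symmetric under
    point reflection.

    Parameters
    ----------
    layer_spec : sequence of (tissue code, outer radius mm), innermost first
        Radii must be non-decreasing.  Defaults to :data:`DEFAULT_LAYERS`.
    resolution : voxel edge length in mm.
    gyrus_spec : optional gray-matter ridges protruding into the CSF shell.
    margin_mm : padding around the outermost shell (default: 6 mm, enough for
        a 4 mm electrode slab plus one voxel).
    """
    if layer_spec is None:
        layer_spec = DEFAULT_LAYERS
    layer_spec = tuple((int(c), float(r)) for c, r in layer_spec)
    if resolution <= 0:
        raise PhantomSpecificationError("resolution must be > 0")
    if not layer_spec:
        raise PhantomSpecificationError("layer_spec must not be empty")
    radii = np.array([r for _, r in layer_spec])
    codes = np.array([c for c, _ in layer_spec], dtype=np.int16)
    if (np.diff(radii) < 0).any():
        raise PhantomSpecificationError("layer radii must be non-decreasing, innermost first")
    widths = np.diff(np.concatenate([[0.0], radii]))
    if (widths[widths > 0] < resolution).any():
        warnings.warn(
            "resolution is coarser than the thinnest shell; that shell may vanish",
            stacklevel=2,
        )

    if margin_mm is None:
        margin_mm = 6.0
    half_extent = radii[-1] + margin_mm
    n_half = int(np.ceil(half_extent / resolution))
    dims = 2 * n_half  # even: voxel centers at +-(k - 1/2) h, symmetric about 0
    origin = np.full(3, -(dims - 1) / 2.0 * resolution)

    ax = origin[0] + np.arange(dims) * resolution
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z)

    idx = np.searchsorted(radii, r.ravel(), side="left")
    labels = np.where(idx < len(radii), codes[np.minimum(idx, len(radii) - 1)], Tissue.BACKGROUND)
    labels = labels.reshape(r.shape).astype(np.int16)

    vol = LabelVolume(labels, resolution, origin)

    if gyrus_spec is not None:
        _carve_gyri(vol, r, x, y, z, gyrus_spec)
    return vol


def _carve_gyri(vol, r, x, y, z, spec: GyrusSpec) -> None:
    """Replace CSF with GM along radial azimuthal sectors (in place)."""
    if spec.count < 1:
        return
    az = np.rad2deg(np.arctan2(x, y))
    incl = np.rad2deg(np.arccos(np.clip(np.divide(z, r, out=np.ones_like(z), where=r > 0), -1, 1)))
    centers = (np.arange(spec.count) * 360.0 / spec.count + spec.offset_deg) % 360.0
    in_ridge = np.zeros(vol.labels.shape, dtype=bool)
    for c in centers:
        d = np.abs((az - c + 180.0) % 360.0 - 180.0)
        in_ridge |= d <= spec.width_deg / 2.0
    in_ridge &= (incl >= spec.incl_range_deg[0]) & (incl <= spec.incl_range_deg[1])
    sel = in_ridge & (vol.labels == Tissue.CSF)
    vol.labels[sel] = Tissue.GM


def gyral_ridge_mask(vol: LabelVolume, spec: GyrusSpec) -> np.ndarray:
    """Boolean mask of voxels inside the angular sectors of ``spec``."""
    cx, cy, cz = vol.voxel_centers()
    x, y, z = np.meshgrid(cx, cy, cz, indexing="ij")
    cc = vol.center
    x, y, z = x - cc[0], y - cc[1], z - cc[2]
    r = np.sqrt(x * x + y * y + z * z)
    az = np.rad2deg(np.arctan2(x, y))
    incl = np.rad2deg(np.arccos(np.clip(np.divide(z, r, out=np.ones_like(z), where=r > 0), -1, 1)))
    centers = (np.arange(spec.count) * 360.0 / spec.count + spec.offset_deg) % 360.0
    mask = np.zeros(vol.labels.shape, dtype=bool)
    for c in centers:
        d = np.abs((az - c + 180.0) % 360.0 - 180.0)
        mask |= d <= spec.width_deg / 2.0
    mask &= (incl >= spec.incl_range_deg[0]) & (incl <= spec.incl_range_deg[1])
    return mask


# ---------------------------------------------------------------------------
# white-matter tensor field

def generate_wm_tensor_field(
    vol: LabelVolume,
    anisotropy_ratio: float = 10.0,
    fiber_pattern: str = "radial",
    base_diffusivity: float = 1.0,
) -> TensorField:
    """Synthetic diffusion-like tensors on the white-matter voxels.

    The principal eigenvector follows ``fiber_pattern`` relative to the
    phantom center ("radial" or "tangential"); the longitudinal:transverse
    eigenvalue ratio is ``anisotropy_ratio``.  Absolute diffusivity units are
    arbitrary — downstream conductivity mapping rescales tensors to a tissue
    target, so only eigenvectors and eigenvalue ratios matter.
    """
    if anisotropy_ratio < 1:
        raise PhantomSpecificationError("anisotropy_ratio must be >= 1")
    if fiber_pattern not in ("radial", "tangential"):
        raise PhantomSpecificationError(f"unknown fiber_pattern {fiber_pattern!r}")
    mask = vol.labels == Tissue.WM
    if not mask.any():
        raise PhantomSpecificationError("volume contains no white-matter voxels")

    cx, cy, cz = vol.voxel_centers()
    x, y, z = np.meshgrid(cx, cy, cz, indexing="ij")
    cc = vol.center
    pos = np.stack([x - cc[0], y - cc[1], z - cc[2]], axis=-1)[mask]
    r = np.linalg.norm(pos, axis=1)
    radial = np.where(r[:, None] > 0, pos / np.maximum(r, 1e-300)[:, None], [[0.0, 0.0, 1.0]])

    if fiber_pattern == "radial":
        e1 = radial
    else:
        # tangential: principal direction perpendicular to the radius, chosen
        # as the local "east" direction (continuous away from the poles)
        up = np.array([0.0, 0.0, 1.0])
        e1 = np.cross(up, radial)
        n = np.linalg.norm(e1, axis=1)
        degenerate = n < 1e-12
        e1[degenerate] = [1.0, 0.0, 0.0]
        n[degenerate] = 1.0
        e1 /= n[:, None]

    lam_long = base_diffusivity * anisotropy_ratio
    lam_trans = base_diffusivity
    outer = np.einsum("ni,nj->nij", e1, e1)
    eye = np.eye(3)[None, :, :]
    tensors = lam_trans * (eye - outer) + lam_long * outer
    return TensorField(mask, tensors)


# ---------------------------------------------------------------------------
# electrode placement

class ElectrodePlacementError(RuntimeError):
    """Raised when a patch cannot be placed on the labeled surface."""


def _patch_footprint_mask(
    vol: LabelVolume, patch: ElectrodePatch, r: np.ndarray, pos_unit: np.ndarray
) -> np.ndarray:
    """Geodesic-rectangle footprint test for every voxel direction.

    Uses azimuthal-equidistant coordinates about the patch center: the long
    axis runs along the local azimuthal ("east") direction, so the flat patch
    wraps the curved scalp with its geodesic side lengths preserved.
    """
    c = direction_from_angles(*patch.position)
    # local frame: u = east (azimuthal), v = north (toward vertex)
    up = np.array([0.0, 0.0, 1.0])
    u = np.cross(up, c)
    if np.linalg.norm(u) < 1e-12:  # patch at a pole: pick arbitrary frame
        u = np.array([1.0, 0.0, 0.0])
    u = u / np.linalg.norm(u)
    v = np.cross(c, u)

    cosg = np.clip(pos_unit @ c, -1.0, 1.0)
    gamma = np.arccos(cosg)
    t = pos_unit - cosg[:, None] * c[None, :]
    tn = np.linalg.norm(t, axis=1)
    t = np.divide(t, np.maximum(tn, 1e-300)[:, None])
    # geodesic offsets (mm) on the sphere of radius r
    xg = r * gamma * (t @ u)
    yg = r * gamma * (t @ v)
    return (np.abs(xg) <= patch.width_mm / 2.0) & (np.abs(yg) <= patch.height_mm / 2.0)


def place_electrode_patches(vol: LabelVolume, montage: Montage) -> LabelVolume:
    """Relabel background voxels above the skin surface into electrode slabs.

    Each patch occupies its geodesic footprint on the scalp and extends
    ``thickness_mm`` radially above the local skin surface.  Only background
    voxels are relabeled, so electrodes touch nothing but background and skin.
    """
    out = vol.copy()
    if not montage.patches:
        return out

    cx, cy, cz = vol.voxel_centers()
    x, y, z = np.meshgrid(cx, cy, cz, indexing="ij")
    cc = vol.center
    pos = np.stack([x - cc[0], y - cc[1], z - cc[2]], axis=-1).reshape(-1, 3)
    r = np.linalg.norm(pos, axis=1)
    pos_unit = np.divide(pos, np.maximum(r, 1e-300)[:, None])

    labels_flat = vol.labels.ravel()
    placed_masks: list[np.ndarray] = []
    for patch in montage.patches:
        foot = _patch_footprint_mask(vol, patch, r, pos_unit)
        surf_sel = foot & (labels_flat != Tissue.BACKGROUND)
        if not surf_sel.any():
            raise ElectrodePlacementError(
                f"patch at {patch.position} has no labeled surface under its footprint"
            )
        r_surface = r[surf_sel].max()  # outermost labeled voxel center in footprint
        slab = foot & (labels_flat == Tissue.BACKGROUND) & (r <= r_surface + patch.thickness_mm)
        if not slab.any():
            raise ElectrodePlacementError(
                f"patch at {patch.position} produced an empty electrode slab"
            )
        for prev in placed_masks:
            if (prev & slab).any():
                raise PhantomSpecificationError("electrode patch footprints overlap")
        placed_masks.append(slab)
        out.labels.ravel()[slab] = patch.code
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O

def save_label_volume(vol: LabelVolume, path) -> None:
    """Write the label volume as an integer NIfTI; voxel size in the header,
    origin in the affine."""
    affine = np.eye(4)
    affine[:3, :3] *= vol.voxel_size
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.labels.astype(np.int16), affine)
    img.header.set_zooms((vol.voxel_size,) * 3)
    nib.save(img, str(path))


def load_label_volume(path) -> LabelVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise PhantomSpecificationError("only isotropic voxels are supported")
    labels = np.asarray(img.dataobj, dtype=np.int16)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return LabelVolume(labels, float(zooms[0]), origin)
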