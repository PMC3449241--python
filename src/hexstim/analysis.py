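"""Post-processing: tissue statistics, focality, tACS view, montage pipeline.

Statistics of the current-density magnitude |J| are element-volume weighted,
since geometry-adapted elements differ slightly in volume.  Skin and CSF are
flagged ``masked_for_visualization``: their current densities dwarf the
intracranial pattern (shunting), so viewers conventionally hide them — they
are still reported numerically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import sindg

from . import meshing
from .conductivity import TissueTable, assign_conductivity
from .fem import StimulationSolution, solve_montage
from .meshing import HexMesh, element_volumes, geometry_adapt, save_mesh, voxels_to_hex_mesh
from .phantom import (
    GyrusSpec,
    LabelVolume,
    Montage,
    Tissue,
    generate_sphere_phantom,
    generate_wm_tensor_field,
    gyral_ridge_mask,
    place_electrode_patches,
    save_label_volume,
    standard_montage,
)

logger = logging.getLogger("hexstim")

__all__ = [
    "TissueStats",
    "ROISector",
    "MontageReport",
    "PipelineConfig",
    "tissue_statistics",
    "efield_magnitude",
    "focality_metric",
    "tacs_waveform_view",
    "gyral_hotspot_contrast",
    "run_pipeline",
    "DEFAULT_ROIS",
    "jmag_to_volume",
]

TISSUE_NAMES = {
    Tissue.SKIN: "skin",
    Tissue.SKULL_COMPACTA: "skull_compacta",
    Tissue.SKULL_SPONGIOSA: "skull_spongiosa",
    Tissue.CSF: "csf",
    Tissue.GM: "gm",
    Tissue.WM: "wm",
    Tissue.ELECTRODE_ANODE: "anode",
    Tissue.ELECTRODE_CATHODE: "cathode",
}

#: Tissues whose |J| is hidden in visualizations (shunting swamps the scale).
MASKED_TISSUES = (Tissue.SKIN, Tissue.CSF)


class AnalysisError(ValueError):
    pass


@dataclass
class TissueStats:
    tissue: int
    name: str
    peak: float
    mean: float
    p50: float
    p95: float
    p999: float
    element_count: int
    peak_element: int
    masked_for_visualization: bool


@dataclass(frozen=True)
class ROISector:
    """Angular sector of the GM shell, schematic stand-in for a cortical lobe.

    Membership: ``az_halfwidth_min <= |azimuth - az_center| <= az_halfwidth``
    and inclination within ``[incl_min, incl_max]`` (degrees).
    """

    name: str
    az_center: float
    az_halfwidth: float
    az_halfwidth_min: float = 0.0
    incl_min: float = 0.0
    incl_max: float = 180.0

    def contains(self, incl_deg: np.ndarray, az_deg: np.ndarray) -> np.ndarray:
        d = np.abs((az_deg - self.az_center + 180.0) % 360.0 - 180.0)
        return (
            (d >= self.az_halfwidth_min)
            & (d <= self.az_halfwidth)
            & (incl_deg >= self.incl_min)
            & (incl_deg <= self.incl_max)
        )


DEFAULT_ROIS: dict[str, ROISector] = {
    "frontal": ROISector("frontal", 0.0, 60.0, incl_max=100.0),
    "occipital_medial": ROISector("occipital_medial", 180.0, 30.0),
    "occipital_lateral": ROISector("occipital_lateral", 180.0, 75.0, az_halfwidth_min=30.0),
}


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    target = q * cw[-1]
    return float(np.interp(target, cw, v))


def tissue_statistics(solution: StimulationSolution, mesh: HexMesh) -> dict[int, TissueStats]:
    """Element-volume-weighted |J| statistics per tissue."""
    jmag = np.linalg.norm(solution.current_density, axis=1)
    vols = element_volumes(mesh)
    out: dict[int, TissueStats] = {}
    for code in np.unique(mesh.element_label):
        code = int(code)
        sel = mesh.element_label == code
        v = jmag[sel]
        w = vols[sel]
        peak_local = int(np.argmax(v))  # argmax: first (lowest-index) maximum
        out[code] = TissueStats(
            tissue=code,
            name=TISSUE_NAMES.get(code, str(code)),
            peak=float(v[peak_local]),
            mean=float(np.average(v, weights=w)),
            p50=_weighted_quantile(v, w, 0.50),
            p95=_weighted_quantile(v, w, 0.95),
            p999=_weighted_quantile(v, w, 0.999),
            element_count=int(sel.sum()),
            peak_element=int(np.nonzero(sel)[0][peak_local]),
            masked_for_visualization=code in MASKED_TISSUES,
        )
    return out


def efield_magnitude(j_magnitude: float, sigma: float):
    """Electric-field magnitude in microvolt/mm from |J| (A/m^2) and sigma (S/m).

    E = J / sigma in V/m; 1 V/m = 1000 microvolt/mm.
    """
    if np.any(np.asarray(sigma) <= 0):
        raise AnalysisError("sigma must be > 0")
    return j_magnitude / sigma * 1000.0


def _element_angles(mesh: HexMesh) -> tuple[np.ndarray, np.ndarray]:
    rel = mesh.element_centroids() - mesh.center_m
    r = np.linalg.norm(rel, axis=1)
    incl = np.rad2deg(np.arccos(np.clip(rel[:, 2] / np.maximum(r, 1e-300), -1, 1)))
    az = np.rad2deg(np.arctan2(rel[:, 0], rel[:, 1]))
    return incl, az


def focality_metric(
    solution: StimulationSolution,
    mesh: HexMesh,
    roi: ROISector,
    threshold: float = 0.5,
) -> tuple[float, float, float]:
    """(focality fraction, target mean |J|, off-target mean |J|) over GM.

    Focality fraction: GM volume with |J| >= ``threshold`` * GM peak, divided
    by total GM volume — smaller means more focal.  Target/off-target means
    are volume-weighted over GM inside/outside the ROI sector.
    """
    gm = mesh.element_label == Tissue.GM
    if not gm.any():
        raise AnalysisError("mesh has no gray-matter elements")
    jmag = np.linalg.norm(solution.current_density, axis=1)
    vols = element_volumes(mesh)
    peak = jmag[gm].max()
    if peak == 0:
        frac = 1.0
    else:
        hot = gm & (jmag >= threshold * peak)
        frac = float(vols[hot].sum() / vols[gm].sum())

    incl, az = _element_angles(mesh)
    in_roi = gm & roi.contains(incl, az)
    if not in_roi.any():
        raise AnalysisError(f"ROI {roi.name!r} contains no gray-matter elements")
    out_roi = gm & ~roi.contains(incl, az)
    target_mean = float(np.average(jmag[in_roi], weights=vols[in_roi]))
    off_mean = (
        float(np.average(jmag[out_roi], weights=vols[out_roi])) if out_roi.any() else 0.0
    )
    return frac, target_mean, off_mean


def tacs_waveform_view(
    solution: StimulationSolution, phase: float, amplitude_scale: float = 1.0
) -> StimulationSolution:
    """The quasistatic tACS field at a sinusoid phase (degrees in [0, 360)).

    Alternating stimulation is the DC solution modulated by
    ``amplitude_scale * sin(phase)``: at phases 180 degrees apart every
    current vector is exactly negated (the flow direction flips by 180
    degrees each half-wave); magnitudes follow |sin|.
    """
    if not (0.0 <= phase < 360.0):
        raise AnalysisError("phase must lie in [0, 360)")
    return solution.scaled(amplitude_scale * float(sindg(phase)))


def gyral_hotspot_contrast(
    solution: StimulationSolution,
    mesh: HexMesh,
    gyrus_spec: GyrusSpec,
    gm_outer_radius_mm: float,
    csf_outer_radius_mm: float,
) -> tuple[float, float]:
    """(mean |J| in protruding GM, mean |J| in equally deep non-ridge GM).

    Protruding GM: ridge elements inside the former CSF band.  Reference:
    the outermost GM band of equal thickness just below the GM/CSF interface,
    outside the ridge sectors — i.e. gray matter at the same depth below the
    local brain surface, but not protruding.
    """
    if mesh.voxel_ijk is None:
        raise AnalysisError("mesh lacks voxel bookkeeping")
    vol_like = LabelVolume(
        np.zeros(mesh.grid_shape, dtype=np.int16), mesh.voxel_size_mm, mesh.origin_mm
    )
    ridge_vox = gyral_ridge_mask(vol_like, gyrus_spec)
    in_ridge = ridge_vox[tuple(mesh.voxel_ijk.T)]

    rel = mesh.element_centroids() - mesh.center_m
    r_mm = np.linalg.norm(rel, axis=1) * meshing.MM_PER_M
    gm = mesh.element_label == Tissue.GM
    band = csf_outer_radius_mm - gm_outer_radius_mm
    protruding = gm & in_ridge & (r_mm > gm_outer_radius_mm)
    reference = gm & ~in_ridge & (r_mm > gm_outer_radius_mm - band) & (r_mm <= gm_outer_radius_mm)
    if not protruding.any() or not reference.any():
        raise AnalysisError("no protruding or reference gray-matter elements found")
    jmag = np.linalg.norm(solution.current_density, axis=1)
    vols = element_volumes(mesh)
    return (
        float(np.average(jmag[protruding], weights=vols[protruding])),
        float(np.average(jmag[reference], weights=vols[reference])),
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline

@dataclass
class MontageReport:
    montage: str
    total_current: float
    tissue_stats: dict[int, TissueStats]
    focality_fraction: float
    roi_stats: dict[str, dict[str, float]]
    gm_peak_efield_uv_mm: float
    solver_iterations: int
    solver_residual: float
    n_unknowns: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissue_stats"] = {TISSUE_NAMES.get(k, str(k)): v for k, v in d["tissue_stats"].items()}
        return d


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible multi-montage comparison run."""

    resolution_mm: float = 2.0
    layer_spec: tuple | None = None  # default nested-shell spec
    gyrus: GyrusSpec | None = None
    montages: tuple[str, ...] = ("FPz-Oz", "F7-F8", "Cz-Oz", "P7-P8")
    total_current: float = 1.0e-3
    conductivity_overrides: dict[int, float] = field(default_factory=dict)
    anisotropy_ratio: float | None = None  # None: isotropic WM
    fiber_pattern: str = "radial"
    shift_factor: float = 0.33
    rel_tol: float = 1e-9
    rois: dict[str, ROISector] = field(default_factory=lambda: dict(DEFAULT_ROIS))
    focality_threshold: float = 0.5
    output_dir: str | None = None
    preconditioner: str = "amg"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "gyrus" in raw and isinstance(raw["gyrus"], dict):
            raw["gyrus"] = GyrusSpec(**raw["gyrus"])
        if "rois" in raw and raw["rois"] and isinstance(next(iter(raw["rois"].values())), dict):
            raw["rois"] = {k: ROISector(name=k, **v) for k, v in raw["rois"].items()}
        if "montages" in raw:
            raw["montages"] = tuple(raw["montages"])
        if "conductivity_overrides" in raw:
            raw["conductivity_overrides"] = {
                int(k): float(v) for k, v in raw["conductivity_overrides"].items()
            }
        if "layer_spec" in raw and raw["layer_spec"] is not None:
            raw["layer_spec"] = tuple((int(c), float(r)) for c, r in raw["layer_spec"])
        return cls(**raw)


def build_phantom_mesh(
    config: PipelineConfig, montage: Montage
) -> tuple[LabelVolume, HexMesh]:
    """Phantom -> electrodes -> mesh -> adaptation -> conductivity, one montage."""
    vol = generate_sphere_phantom(
        layer_spec=config.layer_spec, resolution=config.resolution_mm, gyrus_spec=config.gyrus
    )
    vol = place_electrode_patches(vol, montage)
    mesh = voxels_to_hex_mesh(vol)
    if config.shift_factor > 0:
        mesh = geometry_adapt(mesh, vol, config.shift_factor)
    table = TissueTable(config.conductivity_overrides)
    tensors = None
    if config.anisotropy_ratio is not None:
        tensors = generate_wm_tensor_field(
            vol, anisotropy_ratio=config.anisotropy_ratio, fiber_pattern=config.fiber_pattern
        )
    mesh = assign_conductivity(mesh, table, tensors=tensors)
    return vol, mesh


def jmag_to_volume(mesh: HexMesh, current_density: np.ndarray) -> np.ndarray:
    """|J| resampled onto the source voxel grid (background = 0), for NIfTI export."""
    grid = np.zeros(mesh.grid_shape, dtype=np.float64)
    jmag = np.linalg.norm(current_density, axis=1)
    grid[tuple(mesh.voxel_ijk.T)] = jmag
    return grid


def _analyse(
    montage: Montage, mesh: HexMesh, solution: StimulationSolution, config: PipelineConfig
) -> MontageReport:
    stats = tissue_statistics(solution, mesh)
    roi_stats: dict[str, dict[str, float]] = {}
    frac = None
    for name, roi in config.rois.items():
        f, target, off = focality_metric(solution, mesh, roi, config.focality_threshold)
        frac = f if frac is None else frac
        jmag = np.linalg.norm(solution.current_density, axis=1)
        incl, az = _element_angles(mesh)
        in_roi = (mesh.element_label == Tissue.GM) & roi.contains(incl, az)
        roi_stats[name] = {
            "mean_jmag": target,
            "off_target_mean_jmag": off,
            "peak_jmag": float(jmag[in_roi].max()),
        }
    gm_sigma = TissueTable(config.conductivity_overrides)[Tissue.GM]
    gm_peak = stats[Tissue.GM].peak if Tissue.GM in stats else 0.0
    return MontageReport(
        montage=montage.name,
        total_current=montage.total_current,
        tissue_stats=stats,
        focality_fraction=frac,
        roi_stats=roi_stats,
        gm_peak_efield_uv_mm=float(efield_magnitude(gm_peak, gm_sigma)),
        solver_iterations=solution.solver_info.iterations,
        solver_residual=solution.solver_info.relative_residual,
        n_unknowns=solution.solver_info.n_unknowns,
    )


def run_pipeline(config: PipelineConfig) -> list[MontageReport]:
    """Full comparison: for each montage, phantom -> mesh -> solve -> report.

    If ``config.output_dir`` is set, writes per-montage NIfTI |J| volumes and
    HDF5 solutions plus a TSV/JSON comparison table.
    """
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    reports: list[MontageReport] = []
    for name in config.montages:
        logger.info("montage %s: building phantom and mesh", name)
        try:
            montage = standard_montage(name, total_current=config.total_current)
            vol, mesh = build_phantom_mesh(config, montage)
            logger.info(
                "montage %s: %d elements, %d nodes", name, mesh.n_elements, mesh.n_nodes
            )
            solution = solve_montage(
                mesh, montage, rel_tol=config.rel_tol, preconditioner=config.preconditioner
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline failed for montage {name!r}: {exc}") from exc
        logger.info(
            "montage %s: solved %d unknowns in %d iterations (relres %.2e)",
            name,
            solution.solver_info.n_unknowns,
            solution.solver_info.iterations,
            solution.solver_info.relative_residual,
        )
        report = _analyse(montage, mesh, solution, config)
        reports.append(report)
        if outdir:
            tag = name.replace("-", "_")
            grid = jmag_to_volume(mesh, solution.current_density)
            save_label_volume_float(grid, mesh, outdir / f"{tag}_jmag.nii.gz")
            save_mesh(mesh, outdir / f"{tag}_mesh.h5")
            _save_solution(solution, outdir / f"{tag}_solution.h5")
    if outdir:
        write_comparison_table(reports, outdir)
    return reports


def save_label_volume_float(grid: np.ndarray, mesh: HexMesh, path) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] *= mesh.voxel_size_mm
    affine[:3, 3] = mesh.origin_mm
    nib.save(nib.Nifti1Image(grid.astype(np.float32), affine), str(path))


def _save_solution(solution: StimulationSolution, path) -> None:
    import h5py

    with h5py.File(str(path), "w") as f:
        f.create_dataset("potential", data=solution.potential)
        f.create_dataset("current_density", data=solution.current_density)
        f.attrs["iterations"] = solution.solver_info.iterations
        f.attrs["relative_residual"] = solution.solver_info.relative_residual
        f.attrs["n_unknowns"] = solution.solver_info.n_unknowns


def comparison_frame(reports: list[MontageReport]) -> pd.DataFrame:
    """One row per montage x tissue/ROI, for the TSV comparison table."""
    rows = []
    for rep in reports:
        for code, ts in sorted(rep.tissue_stats.items()):
            rows.append(
                {
                    "montage": rep.montage,
                    "region": ts.name,
                    "kind": "tissue",
                    "peak_jmag": ts.peak,
                    "mean_jmag": ts.mean,
                    "p999_jmag": ts.p999,
                    "focality_fraction": rep.focality_fraction,
                    "masked": ts.masked_for_visualization,
                }
            )
        for name, rs in rep.roi_stats.items():
            rows.append(
                {
                    "montage": rep.montage,
                    "region": name,
                    "kind": "roi",
                    "peak_jmag": rs["peak_jmag"],
                    "mean_jmag": rs["mean_jmag"],
                    "p999_jmag": np.nan,
                    "focality_fraction": rep.focality_fraction,
                    "masked": False,
                }
            )
    return pd.DataFrame(rows)


def write_comparison_table(reports: list[MontageReport], outdir) -> None:
    outdir = Path(outdir)
    comparison_frame(reports).to_csv(outdir / "comparison.tsv", sep="\t", index=False)
    with open(outdir / "comparison.json", "w") as f:
        json.dump([r.to_dict() for r in reports], f, indent=2, default=float)
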