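"""Analytic potential for point-current injection on concentric sphere layers.

For a point current source (+I) and sink (-I) on the outer surface of a
piecewise-homogeneous concentric-sphere conductor, the potential separates
into zonal harmonics.  Within layer j the degree-n radial factor is

    R_n(r) = a_j (r / r_j)^n + b_j (r_j / r)^(n+1)

with coefficients linked across interfaces by continuity of the potential and
of the radial current density, regular at the center (b_1 = 0), and fixed at
the outer surface by the harmonic expansion of the point-electrode surface
current density.  The per-layer scaling keeps the recursion numerically
stable up to hundreds of terms.

This closed-form series is the independent correctness standard for the
finite-element solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .meshing import HexMesh
from .phantom import Tissue

__all__ = [
    "SphereModel",
    "layered_sphere_potential",
    "homogeneous_sphere_potential",
    "compare_to_oracle",
    "OracleReport",
]


class OracleError(ValueError):
    pass


@dataclass
class SphereModel:
    """Concentric-layer conductor with surface point electrodes.

    ``layer_radii`` in meters, innermost first, strictly increasing;
    ``layer_conductivities`` in S/m; ``source_dir`` / ``sink_dir`` are unit
    directions of the +I and -I electrodes on the outer surface.
    """

    layer_radii: np.ndarray
    layer_conductivities: np.ndarray
    source_dir: np.ndarray
    sink_dir: np.ndarray
    total_current: float = 1.0e-3

    def __post_init__(self) -> None:
        self.layer_radii = np.asarray(self.layer_radii, dtype=float)
        self.layer_conductivities = np.asarray(self.layer_conductivities, dtype=float)
        if len(self.layer_radii) != len(self.layer_conductivities):
            raise OracleError("radii and conductivities must have equal length")
        if (np.diff(self.layer_radii) <= 0).any() or self.layer_radii[0] <= 0:
            raise OracleError("layer radii must be positive and strictly increasing")
        if (self.layer_conductivities <= 0).any():
            raise OracleError("conductivities must be positive")
        self.source_dir = np.asarray(self.source_dir, float)
        self.sink_dir = np.asarray(self.sink_dir, float)
        self.source_dir = self.source_dir / np.linalg.norm(self.source_dir)
        self.sink_dir = self.sink_dir / np.linalg.norm(self.sink_dir)

    @property
    def outer_radius(self) -> float:
        return float(self.layer_radii[-1])


def _radial_coefficients(model: SphereModel, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-layer (a, b) coefficients, shape (n_terms, L), for degrees 1..n_terms.

    Normalized so the outer Neumann condition carries the point-electrode
    surface density expansion  I (2n+1) / (4 pi R^2).
    """
    radii = model.layer_radii
    sig = model.layer_conductivities
    big_r = model.outer_radius
    n_layers = len(radii)
    ns = np.arange(1, n_terms + 1, dtype=float)

    a = np.zeros((n_terms, n_layers))
    b = np.zeros((n_terms, n_layers))
    a[:, 0] = 1.0  # b_1 = 0: regular at the center
    for j in range(n_layers - 1):
        rj, rj1 = radii[j], radii[j + 1]
        t = (rj / rj1) ** ns  # decays with n
        s = (rj1 / rj) ** (ns + 1)  # grows with n, divided out below
        p_val = a[:, j] + b[:, j]
        q_val = sig[j] * (ns * a[:, j] - (ns + 1) * b[:, j])
        sb = (ns * p_val - q_val / sig[j + 1]) / (2 * ns + 1)
        b[:, j + 1] = sb / s
        a[:, j + 1] = (p_val - sb) / t

    # outer boundary: sigma_L dR_n/dr |_R = I (2n+1) / (4 pi R^2)
    deriv = sig[-1] * (ns * a[:, -1] - (ns + 1) * b[:, -1]) / big_r
    c = model.total_current * (2 * ns + 1) / (4 * np.pi * big_r**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = c / deriv
    if not np.isfinite(lam).all():
        raise OracleError("degenerate transfer coefficients in the sphere series")
    return a * lam[:, None], b * lam[:, None]


def _legendre_all(n_max: int, x: np.ndarray) -> np.ndarray:
    """P_n(x) for n = 1..n_max by the three-term recurrence; shape (len(x), n_max)."""
    x = np.asarray(x, dtype=float)
    out = np.empty((len(x), n_max))
    p_prev = np.ones_like(x)
    p = x.copy()
    out[:, 0] = p
    for n in range(1, n_max):
        p_next = ((2 * n + 1) * x * p - n * p_prev) / (n + 1)
        p_prev, p = p, p_next
        out[:, n] = p
    return out


def layered_sphere_potential(
    model: SphereModel, points: np.ndarray, n_terms: int = 200
) -> np.ndarray:
    """Series potential (V) at one or many points inside the sphere.

    Zero-mean gauge on the outer surface (the series has no monopole term).
    Emits a warning if the last terms are not decaying — e.g. when points sit
    too close to a point electrode for the series length.
    """
    if n_terms < 1:
        raise OracleError("n_terms must be >= 1")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    big_r = model.outer_radius
    if (r > big_r * (1 + 1e-9)).any():
        raise OracleError("evaluation point outside the outer sphere")

    a, b = _radial_coefficients(model, n_terms)
    radii = model.layer_radii
    layer_of = np.searchsorted(radii, r, side="left")
    layer_of = np.minimum(layer_of, len(radii) - 1)

    with np.errstate(divide="ignore"):
        unit = np.divide(pts, np.maximum(r, 1e-300)[:, None])
    cos_src = np.clip(unit @ model.source_dir, -1, 1)
    cos_snk = np.clip(unit @ model.sink_dir, -1, 1)
    ang = _legendre_all(n_terms, cos_src) - _legendre_all(n_terms, cos_snk)  # (M, n)
    ang[r == 0] = 0.0  # center: all P_n terms cancel pairwise only for n>=1 anyway

    ns = np.arange(1, n_terms + 1, dtype=float)
    phi = np.zeros(len(pts))
    terms_tail = 0.0
    for j in np.unique(layer_of):
        sel = layer_of == j
        rj = radii[j]
        rr = r[sel, None]
        with np.errstate(divide="ignore", over="ignore"):
            radial = a[None, :, j] * (rr / rj) ** ns[None, :]
            if j > 0:  # innermost layer has b = 0 (regularity at the center)
                radial = radial + b[None, :, j] * (rj / np.maximum(rr, 1e-300)) ** (
                    ns[None, :] + 1
                )
        series = radial * ang[sel]
        phi[sel] = series.sum(axis=1)
        if series.shape[1] >= 20:
            head = np.abs(series[:, : series.shape[1] // 2]).max()
            tail = np.abs(series[:, -5:]).max()
            terms_tail = max(terms_tail, tail / max(head, 1e-300))
    if terms_tail > 1e-3:
        warnings.warn(
            f"sphere series tail not decayed (tail/head = {terms_tail:.2e}); "
            "increase n_terms or move evaluation points away from the electrodes",
            stacklevel=2,
        )
    return phi if np.asarray(points).ndim > 1 else phi[:1][0]


def homogeneous_sphere_potential(
    radius: float,
    sigma: float,
    source_dir: np.ndarray,
    sink_dir: np.ndarray,
    points: np.ndarray,
    total_current: float = 1.0e-3,
) -> np.ndarray:
    """Closed form for a homogeneous sphere with surface point electrodes.

    For a single surface source the series sums to

        Phi = I / (4 pi sigma R) [ 2R/d - 2 + ln( 2R / (R - r cos(g) + d) ) ]

    with d the chordal distance to the electrode and g the polar angle from
    it; the sink contributes the negative.  Shares the series' gauge (no
    monopole term), so it is directly comparable to
    :func:`layered_sphere_potential` — via an independent code path.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.zeros(len(pts))
    for direction, sign in ((source_dir, +1.0), (sink_dir, -1.0)):
        e = np.asarray(direction, float)
        e = e / np.linalg.norm(e)
        b = radius * e
        d = np.linalg.norm(pts - b, axis=1)
        rcos = pts @ e
        term = 2 * radius / d - 2.0 + np.log(2 * radius / (radius - rcos + d))
        out += sign * term
    out *= total_current / (4 * np.pi * sigma * radius)
    return out if np.asarray(points).ndim > 1 else out[:1][0]


@dataclass
class OracleReport:
    """FE-versus-series discrepancy on a sampling shell away from electrodes."""

    rel_l2_potential: float
    max_abs_potential_error: float
    rel_l2_jmag: float
    n_potential_samples: int
    n_j_samples: int
    shell_radius_m: float
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rel_l2_potential": self.rel_l2_potential,
            "max_abs_potential_error": self.max_abs_potential_error,
            "rel_l2_jmag": self.rel_l2_jmag,
            "n_potential_samples": self.n_potential_samples,
            "n_j_samples": self.n_j_samples,
            "shell_radius_m": self.shell_radius_m,
            **self.details,
        }


def _sigma_at_radius(model: SphereModel, r: np.ndarray) -> np.ndarray:
    idx = np.minimum(
        np.searchsorted(model.layer_radii, r, side="left"), len(model.layer_radii) - 1
    )
    return model.layer_conductivities[idx]


def compare_to_oracle(
    solution,
    mesh: HexMesh,
    model: SphereModel,
    shell_radius: float | None = None,
    exclusion_deg: float = 20.0,
    n_terms: int = 200,
) -> OracleReport:
    """Relative L2 error of the FE solution against the analytic series.

    Potentials are compared at mesh nodes on a shell of ``shell_radius``
    (default: 60% of the innermost layer radius), excluding polar caps of
    ``exclusion_deg`` around both electrodes where the point/patch source
    discrepancy dominates.  Both fields are de-meaned over the sample set
    before comparison, removing the gauge difference.  |J| is compared at
    element centroids in the same shell band, against sigma * |grad Phi| of
    the series evaluated by central differences.
    """
    center = mesh.center_m
    if shell_radius is None:
        shell_radius = 0.6 * model.layer_radii[0]
    h = (mesh.voxel_size_mm or 1.0) / 1000.0

    rel = mesh.nodes - center
    r = np.linalg.norm(rel, axis=1)
    cos_excl = np.cos(np.deg2rad(exclusion_deg))
    with np.errstate(invalid="ignore"):
        unit = rel / np.maximum(r, 1e-300)[:, None]
    away = (unit @ model.source_dir < cos_excl) & (unit @ model.sink_dir < cos_excl)
    on_shell = np.abs(r - shell_radius) <= h / 2
    sel = on_shell & away
    if not sel.any():
        raise OracleError("no mesh nodes on the requested comparison shell")

    phi_fe = solution.potential[sel]
    phi_an = layered_sphere_potential(model, rel[sel], n_terms=n_terms)
    phi_fe = phi_fe - phi_fe.mean()
    phi_an = phi_an - phi_an.mean()
    diff = phi_fe - phi_an
    rel_l2 = float(np.linalg.norm(diff) / np.linalg.norm(phi_an))
    max_abs = float(np.abs(diff).max())

    # |J| at element centroids in the shell band
    cent = mesh.element_centroids() - center
    rc = np.linalg.norm(cent, axis=1)
    with np.errstate(invalid="ignore"):
        cunit = cent / np.maximum(rc, 1e-300)[:, None]
    csel = (
        (np.abs(rc - shell_radius) <= h / 2)
        & (cunit @ model.source_dir < cos_excl)
        & (cunit @ model.sink_dir < cos_excl)
    )
    if csel.any():
        pts = cent[csel]
        delta = h / 10.0
        grad = np.empty((len(pts), 3))
        for axis in range(3):
            step = np.zeros(3)
            step[axis] = delta
            grad[:, axis] = (
                layered_sphere_potential(model, pts + step, n_terms=n_terms)
                - layered_sphere_potential(model, pts - step, n_terms=n_terms)
            ) / (2 * delta)
        j_an = _sigma_at_radius(model, np.linalg.norm(pts, axis=1)) * np.linalg.norm(
            grad, axis=1
        )
        j_fe = np.linalg.norm(solution.current_density[csel], axis=1)
        rel_l2_j = float(np.linalg.norm(j_fe - j_an) / np.linalg.norm(j_an))
    else:
        rel_l2_j = float("nan")

    return OracleReport(
        rel_l2_potential=rel_l2,
        max_abs_potential_error=max_abs,
        rel_l2_jmag=rel_l2_j,
        n_potential_samples=int(sel.sum()),
        n_j_samples=int(csel.sum()),
        shell_radius_m=float(shell_radius),
        details={"exclusion_deg": exclusion_deg, "n_terms": n_terms},
    )


def sphere_model_from_mesh(
    mesh: HexMesh,
    layer_spec_mm: tuple[tuple[int, float], ...],
    table: dict[int, float],
    source_dir: np.ndarray,
    sink_dir: np.ndarray,
    total_current: float,
) -> SphereModel:
    """Build the analytic model matching a sphere-phantom mesh's layer spec."""
    present = set(int(v) for v in np.unique(mesh.element_label)) - set(Tissue.ELECTRODES)
    radii = []
    sigmas = []
    for code, r_mm in layer_spec_mm:
        if code not in present:
            raise OracleError(f"mesh has no elements of layer tissue {code}")
        radii.append(r_mm / 1000.0)
        sigmas.append(table[int(code)])
    return SphereModel(
        np.array(radii), np.array(sigmas), source_dir, sink_dir, total_current
    )
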