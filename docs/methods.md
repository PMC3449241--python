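# Methods

## Physical model

Transcranial direct current stimulation (tDCS) drives a weak direct current
(here 1 mA by default) through the head between two scalp electrodes. At
these frequencies (DC to a few hundred Hz) capacitive and inductive effects
are negligible, so the quasistatic approximation of Maxwell's equations
applies: the electric potential Φ satisfies

    ∇ · (σ ∇Φ) = 0        in the head volume,
    (σ ∇Φ) · n̂ = j_n      on the surface,

with σ the 3×3 conductivity tensor field and j_n the normal current density
prescribed on the exposed electrode surfaces (an inhomogeneous Neumann
boundary condition): the integral of j_n over the anode is +I, over the
cathode −I, and zero elsewhere. The current density is J = −σ∇Φ and the
electric field E = J/σ; magnitudes are reported in A/m² and µV/mm
(1 V/m = 1000 µV/mm). Note that the sign convention is the physical one —
current flows from anode to cathode; the magnitude pattern is unaffected by
the sign choice.

Because the problem is linear, Φ and J scale exactly with the injected
current, and alternating stimulation (tACS) in the quasistatic regime is the
DC solution modulated by the waveform: at phases 180° apart every current
vector is exactly negated, which is also what interchanging anode and
cathode does.

## Head phantom

Individual MRI-based head models require a subject's T1/T2/DT-MRI and a
segmentation pipeline, which this package deliberately does not include.
Instead, `hexstim.phantom` generates a six-compartment layered-sphere
phantom that preserves the tissue topology of a segmented head: nested
shells of white matter (WM), gray matter (GM), cerebrospinal fluid (CSF),
and a skull-compacta / spongiosa / compacta sandwich, wrapped in skin.
Default outer radii (mm): WM 64, GM 71, CSF 74, compacta 76, spongiosa 79,
compacta 81, skin 86 — an adult-head scale. The skull-layer split is a
modeling choice; no reference thicknesses are enforced. Each voxel is
labeled by the innermost layer whose outer radius covers its center. The
grid is even-sized and centered, so the lattice (and hence the mesh) is
exactly symmetric under point reflection — useful for symmetry tests, and
important to know when interpreting montage asymmetries (below).

Two optional features emulate anatomy that the smooth shells lack:

* **Gyral ridges** (`GyrusSpec`): angular sectors in which the CSF shell is
  replaced by GM over its full thickness, a schematic stand-in for gyri and
  small structures protruding into CSF. Default: 8 ridges of 10° azimuthal
  width between inclinations 30–150°.
* **WM anisotropy** (`generate_wm_tensor_field`): diffusion-like tensors on
  WM voxels whose principal eigenvector is radial or tangential to the
  phantom center and whose longitudinal:transverse eigenvalue ratio is a
  parameter (≥ 1). Absolute diffusivity is arbitrary by construction, since
  the conductivity mapping normalizes it away.

Electrode patches are geodesic rectangles (default 7 cm × 5 cm × 4 mm,
saline-like 1.4 S/m) placed at 10–20-analog angular positions: vertex = Cz
at inclination 0°, the outer ring at inclination 90°, azimuth measured from
the nasion (0°) positive to the subject's right, giving FPz (90°, 0°),
Oz (90°, 180°), F7/F8 (90°, ∓54°), P7/P8 (90°, ∓126°) by equal-arc spacing
of the 10–20 outer ring. The footprint uses azimuthal-equidistant
coordinates about the patch center (long axis along the local azimuthal
direction), so the geodesic side lengths are preserved; background voxels
within the footprint and within the patch thickness above the local skin
surface are relabeled. Electrodes therefore touch only skin and background.

## Discretization

`hexstim.meshing` converts the label volume to one trilinear hexahedral
element per non-background voxel with shared nodes (vertex ordering: bottom
face counter-clockwise, then top face; coordinates in meters). A single
geometry-adaptation pass then shifts every node that touches a material
interface or the outer boundary toward the centroid of its incident
interface-face centers, clamped per component to `shift_factor` × voxel
size (default 0.33, configurable in [0, 0.49]). This softens the voxel
staircase while provably keeping volumes near the voxel volumes (observed
< 5% total change) and is verified after each adaptation by evaluating the
isoparametric Jacobian determinant at all 2×2×2 Gauss points; any
non-positive determinant aborts with the offending element. The precise
node-shifting rule of published geometry-adapted meshing pipelines is not
reproduced here; the face-centroid scheme is this package's own
approximation with the same intent.

Stiffness assembly uses 2×2×2 Gauss quadrature on trilinear shape
functions — exact for trilinear geometry with one constant conductivity
tensor per element — in deterministic element order, so repeated runs are
bit-identical. The matrix is symmetric positive semidefinite with the
constant vector as its null space; the load vector distributes a uniform
normal current density over each electrode's exposed outer faces (exterior
faces whose outward normal points away from the head center by more than
cos⁻¹ 0.25), splitting each face's current equally among its four nodes and
normalizing polarity sums to ±I exactly. Injecting on the free saline
surface rather than at the skin interface lets the 1.4 S/m patch volume
distribute the current, as a sponge electrode does.

## Conductivity model

Isotropic compartments: skin 0.43, skull compacta 0.007, skull spongiosa
0.025, CSF 1.79, GM 0.24, WM 0.19, electrodes 1.4 S/m (all overridable).
When a WM tensor field is supplied, each WM element receives the
effective-medium conductivity tensor: the diffusion tensor rescaled by one
positive scalar so that the geometric mean of its eigenvalues —
det(σ)^(1/3) — equals the tissue target (volume constraint). This shares
the diffusion eigenvectors, preserves the anisotropy ratio exactly, and
realizes the target mean conductivity per element to machine precision, so
the anisotropy-ratio-1 pipeline coincides with the isotropic one to
< 1e-12. GM anisotropy is off by default but the same mechanism accepts GM
tensors if supplied.

## Solver

The singular-but-consistent Neumann system is solved by conjugate gradients
preconditioned with a smoothed-aggregation multigrid V(1,1)-cycle written
for this package (`hexstim._amg`): nodes are aggregated into 3×3×3 spatial
blocks of the (possibly adapted) voxel-derived lattice, the tentative
piecewise-constant prolongator is smoothed with one damped-Jacobi step
(weight 4/(3ρ), ρ estimated by power iteration), coarse operators are
Galerkin products, and the coarsest level (≤ 400 unknowns) uses a dense
pseudo-inverse that respects the null space. Iterates are kept orthogonal
to the constant vector by de-meaning the preconditioned residual, and the
returned potential is gauged to zero mean (no Dirichlet pin, treating both
electrodes symmetrically). Convergence: ‖Kx − b‖ ≤ rel_tol·‖b‖, default
rel_tol 1e-9, cap 10 000 iterations (typical: ~30 iterations for ~350 000
unknowns at 2 mm). A Jacobi-preconditioned fallback is available and is
also used in tests that rely on preconditioner symmetry under reflection.

## Analytic oracle

For concentric homogeneous layers with point current electrodes on the
outer surface, the potential has a zonal-harmonic expansion whose degree-n
radial factor in layer j is a_j (r/r_j)^n + b_j (r_j/r)^(n+1); continuity
of potential and radial current density links layers, regularity at the
center sets b_1 = 0, and the outer Neumann condition carries the
point-electrode expansion I(2n+1)/(4πR²). The per-layer scaling keeps the
recursion stable to hundreds of terms (default 200, with a tail-decay
diagnostic). Validation solves the FE problem on a voxelized three-layer
sphere (brain/skull/scalp = 0.33/0.0042/0.33 S/m at 78/84/90 mm, the
classic three-shell model) with 2 cm patches approximating point
electrodes, and compares potentials at mesh nodes on a mid-brain shell
(60% of the brain radius), excluding 20° polar caps around the electrodes
where the point/patch discrepancy dominates, after de-meaning both fields
over the sample set (gauge alignment). |J| is compared at element
centroids in the same band against σ|∇Φ| of the series by central
differences. The homogeneous limit of the series is itself checked against
an independently coded closed form.

## Analysis conventions

* Tissue statistics of |J| are element-volume weighted; the 99.9th
  percentile is reported alongside the raw peak because patch-edge elements
  carry discretization singularities. Peak ties break to the lowest element
  index. Skin and CSF are flagged `masked_for_visualization` (their
  shunting currents dwarf the intracranial scale) but reported numerically.
* Focality = GM volume with |J| ≥ 50% of the GM peak, divided by total GM
  volume (half-max volume fraction; smaller = more focal; threshold
  configurable). It is invariant under rescaling of the injected current.
* ROI sectors on the GM shell stand in for lobes: frontal (|azimuth| < 60°,
  inclination < 100°), occipital-medial (|azimuth − 180°| < 30°),
  occipital-lateral (30° ≤ |azimuth − 180°| < 75°); all configurable.
* The gyral hot-spot contrast compares mean |J| in ridge GM inside the
  former CSF band against the outermost non-ridge GM band of equal
  thickness — gray matter at the same depth below the local brain surface
  that does not protrude.

## Montage comparison and the symmetry caveat

The four standard montages (FPz/Oz, F7/F8, Cz/Oz, P7/P8) are compared on
the default phantom at 2 mm. Orderings that depend only on electrode
geometry hold there: the lateral F7/F8 pair delivers a higher frontal-ROI
mean |J| and a much smaller focality fraction than the midline FPz/Oz pair,
and P7/P8 reaches the lateral-occipital ROI more strongly than Cz/Oz.

One reported ordering — FPz/Oz driving a higher occipital than frontal GM
peak — cannot arise on the default phantom: the sphere is exactly
front–back mirror symmetric, so the two peaks tie to solver precision
(measured relative difference ~2e-11). In a real head this ordering comes
from anatomy, specifically occipital gyri adjacent to the interhemispheric
cleft sitting in CSF. The package therefore asserts it on a phantom with a
single posterior midline gyral ridge (20° azimuth at 180°, inclinations
60–120°) — the schematic emulation of exactly that anatomy — where the
ordering holds by a factor ≈ 5.

## What the phantom does and does not show

Passing these checks demonstrates correct field computation (oracle
agreement, conservation, linearity, symmetry) and that the qualitative
mechanisms the montage comparison rests on — scalp and CSF shunting, gyral
hot-spots, lateral-versus-midline focality — emerge from the model. The
phantom has no realistic cortical folding, no front–back or left–right
anatomical asymmetry beyond the optional schematic ridges, and no
individual variability, so absolute per-montage current-density values on
the phantom are not predictions for any head; only orderings and
mechanisms transfer. Frequency-dependent tissue properties, neuronal
polarization, and phosphene physiology are out of scope.

## Problem sizes and numerical defaults

Default production resolution is 2 mm (≈ 3.4 × 10⁵ elements, ~30 CG
iterations, tens of seconds per montage on one core); 1 mm is available
through configuration (≈ 2.7 × 10⁶ elements) when a finer staircase is
wanted. Unit tests run at 4 mm. Tolerances: solver rel_tol 1e-9;
adaptation shift_factor 0.33; oracle series 200 terms; flux conservation
is checked to 2% (elementwise-constant J makes the discrete flux only
approximately conservative); degenerate inputs (empty volumes, missing
tissue entries, incompatible loads, non-SPD tensors, off-surface patches)
raise typed errors rather than producing fields.
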