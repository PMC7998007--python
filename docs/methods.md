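# Methods

## Segmentation model

Each structure is segmented independently as a binary labeling `L` of the
voxel grid minimizing

    E(L) = Σ_{(p,q): L_p ≠ L_q} B(p,q) + λ Σ_p R_p(L_p),
    B(p,q) = exp(−(I_p − I_q)² / 2σ²) / ‖p − q‖_mm,

subject to hard seed constraints. Seed voxels are connected to the
source/sink terminal with capacity `K = 1 + max_p Σ_q B(p,q)`, which
strictly exceeds the energy of any seed-free cut, so foreground seeds are
always labeled and background seeds never are. With `λ > 0`, `R_p` is the
negative log-density of a Gaussian fitted to the foreground/background seed
intensities (variance floored at 1e-6 to survive constant seed regions),
clamped to `[0, K]`.

Assumptions: a structure is separated from its surroundings by an intensity
edge somewhere between its foreground and background seeds; intensities
within a structure are locally homogeneous at the scale of `σ`. The energy
is intentionally the standard seeded-cut formulation — simple, exact, and
fully reproducible from the parameter snapshot in the run manifest.

### Parameters

| parameter | default | units | why |
|---|---|---|---|
| `sigma` | 30 | intensity | ≈ the parenchyma/tumor contrast step of an enhanced T1 after windowing; edges ≥ 2σ cost ≈ e⁻² per link |
| `lambda_regional` | 0 | — | pure boundary + hard seeds; regional terms help only when seeds cannot bracket a structure |
| `connectivity` | 6 | — | face neighbours suffice on isotropic 1-mm grids; 18/26 available |
| `spacing_aware` | on | — | divides links by mm distance so cuts respect anatomy under anisotropic spacing |

### Numerical solution

The cut is solved with `scipy.sparse.csgraph.maximum_flow` on capacities
scaled by 2²⁰ and rounded to 64-bit integers; the foreground is the
source-reachable component of the residual graph. Quantization perturbs the
energy by < n_edges·2⁻²⁰, far below the separation between distinct cut
energies in every test; the optimality suite asserts equality with an
exhaustive-enumeration oracle to 1e-4. Ties between equal-energy cuts are
broken arbitrarily by the flow algorithm; tests assert energy equality, not
voxel identity.

## Preprocessing

Default denoiser: Perona–Malik anisotropic diffusion, 5 iterations,
conductance κ=30, time step 0.1 — it flattens noise without degrading the
intensity edges the boundary term depends on. A median filter over the
6-neighbourhood cross is the deterministic alternative; its neighbourhood
is truncated at the grid boundary (no padding) and the lower median is
taken for even counts, keeping it a pure selection filter everywhere.

## Seeds

Sketch strokes are digital polylines (8-connected in-plane) dilated by a
Chebyshev disc of `brush_radius`; polygons are filled even-odd with voxel
centers exactly on an edge counted inside (stable for integer-coordinate
fixtures); freedraw is a validated explicit pixel set. Seeds live on
axis-aligned slices; a voxel claimed as both foreground and background for
one structure is a hard error naming the voxel.

## Multiplanar reconstruction

Plane samples are `origin + i·s·u + j·s·(n×u)` in mm, trilinear for
intensities and nearest-neighbour for labels (labels must not blend), with
contours traced by 2-D marching squares at 0.5. Sample coordinates within
1e-9 of an integer index are snapped so axis-aligned extraction is
bit-identical to array indexing.

## Model assembly

Overlaps are resolved on voxels, not meshes: each voxel goes to the
highest-priority claiming structure (default order tumor > ventricles >
deep nuclei > parenchyma), which reproduces the subtraction workflow used
before printing and guarantees adjacent parts meet exactly. Surfaces are
marching cubes at 0.5 on the (1-voxel-padded) binary mask; smoothing is
volume-constrained Laplacian (default 5 iterations, λ=0.5). A digital ball
of radius 10 voxels meshes to within 0.6 % of its voxel volume, and the
error shrinks monotonically with radius.

The mold is the Euclidean-distance dilation of the brain envelope by the
wall thickness, minus the brain, split by the centroid plane along a chosen
axis. Euclidean dilation (distance transform with physical sampling) is
metric-correct under anisotropic spacing; note it rounds corners, so its
voxel count is below the Chebyshev (box-dilation) figure — conservation
`|dilated| = |brain| + |part1| + |part2|` is exact either way. The
single-plane split is a minimal stand-in; real molds may need registration
keys, which are out of scope.

## Planning metrics

Tumor depth is the minimum spacing-aware distance from any tumor voxel to
the brain's outer voxel shell; bins are cortex (contact), < 2 cm, 2–4 cm
(40 mm inclusive — the wording of the source scale is ambiguous at exactly
4 cm), and > 4 cm. The size-change score bins the percent change of
craniotomy area relative to the MR-based plan at 25/50/75 % (left-closed
bins; the scale's "2 for a 0–75 % change" is read as the 50–75 % bin, the
only consistent completion of the ladder; changes beyond 100 % stay 3). The
location score bins the Jaccard overlap of the two outlines at 0.90/0.50
(right-closed); normalising by the reference plan's area instead is a
config switch, since the source does not say which convention was used.

## Validation statistics

Fisher's exact test enumerates the hypergeometric distribution of cell *a*
under fixed margins: one-sided is the upper tail from the observed *a*,
two-sided sums all tables with probability ≤ the observed one (with a
1+1e-9 relative guard against float ties). On the 8/28-vs-2/36
posture-change table the one-sided tail is 0.0147 and the two-sided 0.0163.
The 2×2 chi-square uses the closed form
`N(|ad−bc| − N/2·yates)²/(r₁r₂c₁c₂)` with 1 df. Note the uncorrected
statistic's tail systematically undershoots the exact permutation null on
moderate tables (discreteness); the Yates-corrected tail matches a
Monte-Carlo permutation null within 3 standard errors at 10⁵ draws, and
that is the version the property suite pins. Percentages are rounded
half-up to one decimal at display only.

## Phantom

The generator emulates the pipeline's intended substrate, not anatomy: a
64³, 1-mm-isotropic grid; a brain envelope of radius 26 mm whose radius is
modulated by a ±2 mm radial sinusoid (frequency 6) so the surface is
non-convex like gyri — this stresses meshing and mold generation; an 8-mm
hyperintense tumor offset from center (margin depth ≈ 5–7 mm,
"intermediate"); two ventricle ellipsoids; one 4.5-mm deep nucleus. T1-like
class means are background 10, parenchyma 100, ventricles 40, nucleus 135,
tumor 170, so adjacent classes differ by ≥ 3 noise SD at the default σ=5;
T2/FLAIR variants remap the means (bright/suppressed CSF). Noise is
additive Gaussian — Rician bias is not modeled, because contrast-to-noise
is the controlled variable the segmentation tests sweep. The nucleus, at
35 units of contrast, is intentionally marginal for the default energy and
partially collapses toward its seeds — a realistic failure mode kept as-is.

Consequently, passing tests demonstrate correct behaviour under controlled
contrast and stationary Gaussian noise on closed-form geometry; they say
nothing about bias fields, partial-volume gradients, motion, or real anatomy.
Craniotomy fixture pairs are rectangles with analytically placed overlap,
hitting a requested Jaccard within 0.02 and area change within 2 points.

## Test problem sizes

Exhaustive cut enumeration uses ≤ 12 free voxels (≤ 4096 labelings × 20
trials); recovery tests use the default 64³ phantom; Monte-Carlo
permutation uses 10⁵ draws on five tables with N between 100 and 200. The
whole suite runs in well under a minute on one core.

## Known limitations

Simultaneous multi-label cuts, learned appearance models, inter-sequence
registration, bias-field correction, oblique-slice seeding, DICOM writing,
and mesh-level CSG are all out of scope. The "machine-learning threshold"
mode of the original software is not reconstructable from its description;
Otsu's method is a declared stand-in.
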