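# Methods

## Pipeline overview

A binary lumen mask `I_seg : Ω ⊂ ℝ³ → {0,1}` (NIFTI, anisotropic spacing,
world coordinates in mm) passes through five stages:

1. **Image fields.** `I_σ = G_σ ∗ I_seg` (Gaussian, σ in voxel units, default
   2), the edge density `‖∇I_σ‖²` normalized to unit peak, and its spatial
   gradient — the force that attracts the surface to the lumen wall.
   Gradients are spacing-aware central differences (one-sided at the volume
   faces); off-lattice evaluation is trilinear.
2. **Centerline.** Distance-weighted geodesic farthest-point propagation on
   the 26-connected foreground voxel graph: starting from the deepest voxel
   (maximum Euclidean distance transform), the farthest voxel by plain
   geodesic distance is joined to the growing tree by a shortest path whose
   edge costs carry a 1/(EDT + h)² penalty, pulling paths onto the medial
   ridge; each accepted path is recentered onto its cross-section centroid.
   Growth stops when every remaining voxel lies within 1.5 local radii
   (plus a 2-voxel slack for 26-connectivity metric inflation) of the tree,
   so boundary noise cannot sprout spurs. Tips are finally extended along
   their local principal direction to the mask end faces. Local radius is
   the EDT value in mm.
3. **Branch graph.** Skeleton paths between non-degree-2 nodes become
   branches; the trachea (generation 0) is the branch holding the
   largest-radius point (overridable by a world-coordinate hint) and
   generations increase by one per bifurcation. Following the short-branch
   post-processing rule, any child branch with p_c = length / mean radius
   < 0.3 is removed and its children re-attach to its parent, producing a
   fork-type trifurcation; the operation is idempotent and generations are
   recomputed.
4. **Surface fit.** Per branch, octagonal control rings on arc-length
   resampled centerline nodes, oriented by double-reflection
   rotation-minimizing frames; two cubic patches split the circumference
   with shared seam columns (C⁰). Ring radii come from the mask itself (see
   below). The Snakes energy is discretized on the parametric domain and
   evolved semi-implicitly; validation voxelizes the capped surfaces
   (scanline ray parity over the tessellated mesh, 8× control-net density)
   and computes DICE against the input mask.
5. **Morphometry.** Caps collapse the end rings toward the end centerline
   nodes (Bézier in the radial direction, rims shared with the mantle, so
   the boundary is watertight at C⁰ and outward-oriented). Volume by the
   divergence theorem, area by the first-fundamental-form integral, both
   with 4-point Gauss–Legendre per knot span; radii by orthogonal projection
   of a 64 × max(32, 4·segments) parametric sample grid onto the skeleton
   line segments (per-segment min/max/mean, averaged over segments);
   eccentricity √(1 − (r_min/r_max)²), zero for circular sections.

## Template initialization from the image

Skeleton-derived radii (EDT) underestimate the lumen by up to half a voxel,
and with σ = 2 the smoothed image's half level and edge-density ridge are
biased inward by curvature (≈ σ²κ/2, about 0.3 mm for a 3 mm airway). The
templates therefore measure the wall directly: in each ring plane the mask
(smoothed by a deliberately sub-voxel σ of 0.7 voxels, enough to suppress
single-voxel noise without curvature bias) is sampled on a polar grid and
converted to an area-equivalent radius profile r(θ) = √(2∫s ds); the profile
is circularly smoothed (σ = 2 of 64 angular samples) to remove lattice
aliasing while preserving the ellipticity harmonic, and the 8 control radii
per ring are solved by a small least-squares fit so that the traced spline
section reproduces r(θ) — for circular sections this reduces to the fixed
octagon-to-circle correction factors. End rings reuse their neighbor's
radii because end faces contaminate in-plane localization. Directions
opening into a junction are capped at 2.5 local radii. Ring count is
⌈length / median radius⌉ + 3 (minimum 4).

## Discrete gradient flow

Trial/test spaces are spanned by the tensor B-spline basis (unit weights);
the rate potential Ψ[U̇] = ½∫|U̇|² dΩ̂ yields a consistent (non-lumped) mass
Gram matrix M; the stiffness K = α·(first-derivative Gram) +
β·(second-derivative Gram) is assembled by quadrature with seam unknowns
shared between the two patches, so interface control points remain identical
at every step. Parametric derivatives in K are scaled by per-patch template
arc-length constants (c_ξ = mean ‖S_ξ‖, c_η = mean ‖S_η‖ of the initial
surface): α and β then act on dimensionless shape distortion rather than on
absolute branch dimensions, which keeps one parameter set meaningful from
trachea to subsegmental bronchi — without this, the regularization scales
with the squared branch length and collapses long tubes. The image density
is normalized to unit peak for the same reason. Each step solves
`(M/Δt + K) b⁺ = (M/Δt) b + λ/2 Rᵀ W f(S)` with a cached Cholesky
factorization; iteration ends at max_iters = 35 or when the largest control
point moves < 10⁻³ mm, and five consecutive energy increases abort with
diagnostics. With λ = 0 the scheme is unconditionally energy-decreasing.
Under this normalization the flow is a gentle regularizer: most of the
localization accuracy comes from the template measurement, and a surface
initialized on the wall stays there (mean drift ≪ half a voxel over 35
steps).

## Parameters

| name | meaning | default | unit |
|---|---|---|---|
| alpha | membrane (first-derivative) weight | 1e-2 | — |
| beta | bending (second-derivative) weight | 1e-3 | — |
| lam | image-energy weight | 0.1 | — |
| sigma | Gaussian width for I_σ | 2 | voxels |
| dt | fictitious time step | 0.01 | — |
| max_iters | flow steps | 35 | — |
| degree_p/q | patch degrees (C² inside patches) | 3 | — |
| patches_per_segment | circumferential split | 2 | — |
| quad_order | Gauss points per direction per span | 4 | — |

## Phantoms: what they emulate and what they do not

The generator rasterizes analytic solids (straight/elliptic/bent tubes,
Y-bifurcations, dichotomous trees, a short-branch fork with prescribed
p_c) on the CT lattice (0.7 × 0.7 × 0.5 mm default), refusing diameters
under 3 in-plane voxels (2.1 mm), the floor below which clinical masks are
unreliable. Boundary jitter flips voxels within a given distance of the
surface with probability decaying from ~0.25 at the wall, emulating
partial-volume indecision; it is seeded and deterministic. Ground truth
(volume πr²L, lateral area 2πrL, ellipse measures via Ramanujan's
perimeter, expected TAC/GAC = 2^g) is exact.

Passing these tests shows the geometry, topology and numerics are correct
on tubular objects with known answers; it does not show robustness to
features the phantoms lack: airway walls and CT intensities (only binary
masks are modeled), segmentation leakage blobs, mucus plugs, stenoses,
non-convex junction anatomy, or motion artifacts. Cohort-level biological
conclusions are outside what the synthetic suite can certify.

## Numerical choices and degenerate inputs

- Quadrature order 4 per direction per span (exact through degree 7 per
  factor); volume/area integrals use the same rules.
- Tessellation for voxelization at 8× control-net resolution; ray origins
  offset by 10⁻⁴ voxels to dodge edge-on triangle hits; odd crossing pairs
  are dropped.
- Orientation: the construction makes all normals outward; if a signed
  volume still comes out negative the patch orientation is flipped once and
  a persistent negative raises rather than silently taking |V|.
- Masks saved as floats binarize at 0.5 on read; all-zero masks are flagged,
  not rejected, but cannot be fitted. Multi-component masks and long
  skeleton cycles (leakage) raise errors; small 26-connectivity loop
  artifacts (< 6 median edges + 4 max radii) are removed silently.
- A zero local radius falls back to one voxel with a warning; a two-node
  branch is resampled to the minimum 4 rings.
- Solid blobs yield a degenerate single-point skeleton flagged non-tubular.
- Problem sizes: tests and the acceptance script run on phantoms of roughly
  20–60 mm extent (2–150 k foreground voxels); volume-accuracy properties
  are checked at halved spacing where rasterization aliasing is well below
  the tolerances being asserted.

## Statistics

Per (measure, generation, breathing state) cell: Shapiro-Wilk screening and
a two-sided Mann-Whitney U test between two groups, exact when both groups
have ≤ 8 untied observations (appropriate for six subjects per arm),
asymptotic with tie correction otherwise. Branch-level observations by
default, subject-level averaging optional; no multiple-testing correction
by default (raw p < 0.05 flags), Holm adjustment available. Cells with an
empty group are marked untestable rather than dropped.

## Known limitations

- The centerline resolves side branches only when they extend beyond about
  1.5–2 local parent radii; shorter stubs merge into the junction, which is
  consistent with (and subsumed by) the p_c < 0.3 trifurcation rule.
- The octagonal section with uniform weights is an approximation, not an
  exact rational circle; residual section error after the ring fit is below
  1% for circles and a few percent at 2:1 ellipticity.
- Branches are fitted independently: surfaces of adjacent branches overlap
  at junctions, and the DICE union absorbs this; no inter-branch G¹
  continuity is enforced.
- Wall thickness is out of scope by construction — only the luminal surface
  is modeled.
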