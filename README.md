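# siga — Snakes isogeometric analysis of airway lumina

`siga` turns binary segmentations of the bronchial lumen (NIFTI masks from
lung CT) into smooth, closed, multi-patch **NURBS surface models** of every
airway branch, and measures them: luminal volume, surface area, the
surface-area-to-volume ratio (SA:V), minimum/average/maximum radii, luminal
eccentricity, branch length, and airway counts per generation (TAC/GAC).
It is written for quantitative-imaging researchers studying airway
remodeling — e.g., comparing pre-COPD smokers against mild COPD patients at
end-expiration and end-inspiration — who need sub-voxel geometric measures
that voxel counting alone cannot provide.

## The model

Each airway segment (skeleton path between bifurcation nodes) is represented
by two cubic tensor-product NURBS patches

S_ρ(ξ, η) = Σ_i Σ_j R_ij^{p,q}(ξ, η) **b**_ij,  ρ = 1, 2,

whose control net is a sweep of octagonal rings (8 control points each)
along the branch centerline, transported with rotation-minimizing frames.
The surface is evolved as an active surface ("Snakes"): it minimizes

E(S) = α/2 ∫ (‖S_ξ‖² + ‖S_η‖²) + β/2 ∫ (‖S_ξξ‖² + ‖S_ξη‖² + ‖S_ηη‖²)
     − λ/2 ∫ ‖∇(G_σ ∗ I_seg)(S)‖²,

where `I_seg` is the binary mask and `G_σ` a Gaussian of width σ voxels.
The L² gradient flow of E is discretized semi-implicitly: each fictitious
time step solves one SPD linear system `(M/Δt + K) b⁺ = (M/Δt) b + F(b)`.
Defaults are the calibrated values α = 10⁻², β = 10⁻³, λ = 0.1, σ = 2,
Δt = 0.01 with at most 35 iterations, degrees p = q = 3.

Branches are closed with inlet/outlet cap patches sharing the end-ring
control points, and measured exactly on the parametric surfaces with
Gauss–Legendre quadrature; the volume uses the divergence theorem,
`volume = 1/3 Σ_ρ ∫ X·n ĝ dΩ̂`. Luminal eccentricity is
`eccen = √(1 − (r_min/r_max)²)`. Surface quality is scored by the DICE
overlap between the input mask and the voxelized model
(`DICE = 2|I_seg ∩ I_siga| / (|I_seg| + |I_siga|)`, with ≥ 0.7 the
conventional acceptability threshold).

Because no clinical masks ship with the package, a phantom module
rasterizes tubes, bent tubes, elliptic tubes, Y-bifurcations and dichotomous
trees with closed-form ground truth, on the study's anisotropic CT lattice
(0.7 × 0.7 × 0.5 mm).

## Worked example

```python
from siga import PhantomSpec, SigaParams, fit_mask, generate, measure_tree

img, truth, _ = generate(PhantomSpec(kind="cylinder", radius=3.0, length=20.0,
                                     noise=0.5, seed=1))
result = fit_mask(img, params=SigaParams())
print(f"DICE = {result.dice:.4f}")
table = measure_tree(result.surfaces, result.graph)
print(table[["generation", "volume_mm3", "sa_v_mm-1", "eccen", "length_mm"]].round(2))
```

prints

```
DICE = 0.9302
   generation  volume_mm3  sa_v_mm-1  eccen  length_mm
0           0      562.98       0.77   0.51       19.5
```

The fitted surface overlaps 93% of the noisy mask (an ideal r = 3 mm,
L = 20 mm cylinder has volume πr²L = 565.5 mm³ and SA:V = 2/r + 2/L =
0.767 mm⁻¹; the jittered rasterization and the octagonal section account
for the small residuals). More narrative scripts live in `examples/`
(phantoms and airway counts, fitting, tree morphometry, two-group
Mann-Whitney statistics), and a thin CLI (`siga phantom / fit / measure /
compare`) wraps the same functions for shell use.

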