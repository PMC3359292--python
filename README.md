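# cellscale

Multi-scale finite-element coupling from joint-level loading to chondrocyte
deformation.

Cartilage cells (chondrocytes) respond to the mechanical loading of the
joint they live in, but no experiment can watch a human knee and its cells
deform at the same time.  `cellscale` implements the post-processing route
to bridge those scales: take a converged macro-scale hexahedral FE solution
of a joint, sample the deformation gradient **F** on every element of
interest, drive an independent micro-scale model of a cartilage block —
spherical chondrocytes, each wrapped in a pericellular matrix (PCM) shell,
embedded in extracellular matrix (ECM) — with the affine boundary
displacements **u**(X) = (**F** − **I**) X, and reduce each micro solution
to the cell-level deformation metrics an experimentalist would measure.
Because every micro model is independent, thousands of them parallelize
trivially, and one diverging model never takes the batch down.

Intended users: biomechanics researchers post-processing joint/tissue FE
solutions into cellular deformation estimates, and anyone needing a
self-contained, displacement-driven finite-strain hexahedral solver with
scriptable batch orchestration.

## The model in brief

**Scale coupling.**  For a trilinear hexahedral element with undeformed
nodal positions X_a and deformed positions x_a, the deformation gradient at
natural point ξ is

    F(ξ) = (∂x/∂ξ) (∂X/∂ξ)⁻¹,

evaluated at the element centroid (or the eight 2×2×2 Gauss points to
quantify within-element variation as the maximum over the 28 tensor pairs
of Σᵢⱼ|ΔFᵢⱼ|).  Elements with maxᵢⱼ|Fᵢⱼ − δᵢⱼ| above a threshold (default
10⁻³) warrant a micro model.

**Micro constitutive model.**  Uncoupled Mooney–Rivlin,
W = c₁(Ī₁−3) + c₂(Ī₂−3) + (K/2)(ln J)², with per-region constants (MPa)

| region | c₁     | c₂ | K       |
|--------|--------|----|---------|
| ECM    | 1.6892 | 0  | 83.3333 |
| PCM    | 0.6838 | 0  | 1.0570  |
| Cell   | 0.0405 | 0  | 1.9980  |

The ECM matches the macro-scale cartilage (instantaneous modulus 10 MPa,
ν = 0.48).  The construct is a 100 μm cube; cells have radius 7.5 μm with a
3.3 μm PCM shell, so the ECM occupies 99.5 % (single chondron) or 94.2 %
(eleven chondrons) of the block.

**Metrics** (per cell, volume-averaged where applicable): volumetric strain
(ΣV_def − ΣV_und)/ΣV_und; change in aspect ratio from the ellipsoid of best
fit, obtained by inverting the principal moments λ₁ ≥ λ₂ ≥ λ₃ of the
unit-density inertia tensor, a² = (5/2m)(λ₁+λ₂−λ₃) and permutations;
effective (von Mises) stress/strain √(((p₁−p₂)² + (p₂−p₃)² + (p₁−p₃)²)/2);
and maximum shear strain (p₁−p₃)/2 — stress from the Cauchy tensor, strain
from Green–Lagrange E = ½(FᵀF − I), averaged with deformed element volumes
as weights.

## Worked example

Solve the classic single-cell construct under a 10 % nominal compression
with volume-preserving lateral expansion
(**F** = diag(0.9^−½, 0.9^−½, 0.9)):

```sh
$ cellscale solve-one --cells 1 --resolution 20 \
    --f "1.0540926,0,0,0,1.0540926,0,0,0,0.9"
status: converged
Cell_1: volumetric_strain=-0.0120, dAR_maj_min=0.3900, dAR_maj_mid=0.0000,
        dAR_mid_min=0.3900, effective_strain=0.3040, effective_stress=0.0502,
        max_shear_strain=0.1648
```

Reading the numbers: the imposed macro deformation is isochoric, yet the
cell still loses 1.2 % of its volume (the compressible PCM absorbs it); the
cell's aspect ratio (major/minor) grows by 0.390 even though the boundary
deformation alone would reshape a sphere by only 0.171 — the soft cell
amplifies the imposed deformation roughly two-fold, which is also visible
in the cell effective strain (0.304) against the ECM average (≈ 0.15).
`dAR_maj_mid = 0` reflects the axisymmetry of this load case.

The same flow scales to a whole macro solution:

```sh
cellscale extract-f macro.vtk --set-name cartilage --out F_table.csv
cellscale batch macro.vtk --set-name cartilage --config run.json \
    --workers 8 --out results.csv --manifest manifest.json
cellscale report results.csv      # per-cell through-origin regression slopes
cellscale sensitivity --cells 11  # material-scaling study
```

Macro input is a legacy-VTK unstructured grid (hex cells, optional
`displacement` point-data vector) or CSV tables (`nodes.csv`: id,x,y,z;
`elements.csv`: id,n0..n7[,set]; comma-separated, header row, 0-based
indices).  Macro coordinates are mm, micro coordinates μm; **F** is
dimensionless so nothing is converted across the interface.

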