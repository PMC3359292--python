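# Methods

This note records the modelling and numerical choices behind `cellscale`,
what the synthetic fixtures do and do not emulate, and the known
limitations.

## Scale coupling

The pipeline is a one-way (post-processing) coupling: the macro solution is
fixed, and each macro element's deformation gradient becomes the affine
boundary condition of one micro model, u(X) = (F − I)·X on all six faces of
the construct.  This models the local finite strain as a first-order Taylor
expansion of the macro deformation; gradients of F across a macro element
are not transmitted.  The `gauss8` sampling scheme and the pairwise
variation residual (maximum over the 28 unique pairs of the eight
Gauss-point tensors of the summed absolute component differences) exist
precisely to quantify that truncation per element.

Deformation gradients are computed isoparametrically,
F = (∂x/∂ξ)(∂X/∂ξ)⁻¹, with VTK hexahedron node ordering.  Any consistent
ordering gives the same F; VTK's was chosen for interoperability with mesh
files.  The computation is exact for affine fields at any sampling point
(verified to 1e−12 in the tests) and first-order accurate or better for
smooth non-affine fields (a pure-bending fixture shows O(h²) centroid
error).

Elements are passed to the micro stage when any component of F departs from
the identity by more than `deformation_tol`.  The threshold defaults to
1e−3: small enough that any mechanically meaningful strain (≥ 0.1 % in a
component) is kept, large enough to exclude solver noise in rigid-ish
regions.  It is a run-configuration parameter, not a constant.

## Micro construct

Geometry: a 100 μm cube of ECM containing spherical cells of radius 7.5 μm,
each wrapped in a 3.3 μm PCM shell (chondron radius 10.8 μm).  These
dimensions reproduce the reported ECM volume fractions of the two canonical
constructs — 99.5 % with one chondron and 94.2 % with eleven — to the
printed rounding, and are mutually consistent with a mesh that puts nine
elements across a cell diameter and two through the PCM.  The N-cell
construct places chondrons by seeded rejection sampling under two
constraints, both defaulting to one PCM thickness: minimum surface-to-
surface separation between chondrons and minimum clearance to the block
boundary.  A fixed integer seed makes the geometry bitwise reproducible and
is recorded in the model provenance; a batch reuses one geometry for every
macro element so that row-to-row differences reflect the passed F alone.

Meshing is voxel-based: a structured r×r×r hex grid, each element labelled
ECM/PCM/Cell by the region containing its centroid.  This deviates from a
boundary-conforming sphere mesh deliberately — it is robust for arbitrary
random N-cell geometries and trivially reproducible.  The price is
geometric: labelled region volumes converge to the analytic sphere/shell
volumes only as r grows (measured cell-volume bias ≈ 6 % at r = 50, < 3 %
at r = 80), and at coarse r the thin PCM shell is under a voxel thick.
Resolution-convergence tests substitute for geometric conformity.
Consequences of under-resolving the PCM are discussed under Limitations.

## Constitutive model and solver

Uncoupled Mooney–Rivlin: W = c₁(Ī₁−3) + c₂(Ī₂−3) + U(J) with
U(J) = (K/2)(ln J)².  The volumetric form follows the solver lineage the
material constants come from; it is well-behaved in strong compression.
All reference regions have c₂ = 0, but the c₂ term is implemented and
verified (stress against finite differences of the energy; consistent
tangent against finite differences of the internal force).

Element technology: trilinear hexahedra with selective reduced integration
— isochoric stress and tangent at the 2×2×2 Gauss points, volumetric terms
at the centroid only (one-point mean dilatation).  Full integration locks
at the ECM's near-incompressibility (ν ≈ 0.48) and the cell's K/c₁ ≈ 49;
the selective scheme passes the patch test for every region material and
reproduces the semi-analytic uniaxial solution to < 0.5 % on a 3³ mesh.

Equilibrium is solved by Newton–Raphson under incremental loading
(default 10 equal increments; heavy batch runs use 1–2 because the adaptive
controller below makes more increments redundant).  Each increment is
driven through the tangent — the predictor solves
K_ff δ = −(R_f + K_fp Δu_p), extending the prescribed boundary motion
smoothly into the interior, which is what lets a boundary displacement
larger than the boundary voxel size be applied without inverting elements.
An increment that still tangles the mesh or fails to converge is halved and
retried (down to 1/1024 of the nominal increment, configurable); corrector
iterations use a backtracking line search that accepts only untangled
configurations.  Convergence is declared when the free-DOF residual norm
falls below `tol` (default 1e−6) times the norm of the full internal-force
vector.

Linear solves: below ~15k free DOF, direct sparse LU.  Above it, GMRES on
the symmetrically diagonal-scaled system (the cell/ECM stiffness contrast
spans a factor ~40) preconditioned with an incomplete LU
(drop tolerance 2e−3, fill factor 5, symmetric-mode ordering, no pivoting).
The preconditioner is reused across Newton iterations, load steps, and
repeated solves of the same model/material pair, and rebuilt lazily when
the inner iteration count degrades.  The inner relative tolerance (1e−4)
is an inexact-Newton setting; outer convergence is always judged on the
true residual.  Assembly is vectorized over all elements with a
fixed-sparsity-pattern mapping, so one tangent assembly of a 27k-element
construct takes ~2 s.

Mechanical non-convergence is a *result*, not an exception: the solution
comes back with `status="failed"` and diagnostics, and a batch records the
failure and moves on.  Only structural errors (missing materials, no
constraints, tangled input mesh) raise.

## Metrics

Element volumes use the centroid rule V = 8·det J(0) in both
configurations — exact whenever det J is constant across the element, which
holds for every undeformed voxel and for affinely deformed ones; a 2×2×2
Gauss rule (exact for any trilinear hex) is available for accuracy studies.
The inertia tensor lumps element volumes at element centroids about the
set's volume centroid; the solid-ellipsoid inversion maps its descending
principal moments to semi-axes a ≥ b ≥ c via a² = (5/2m)(λ₁+λ₂−λ₃) and
permutations (the longest axis carries the smallest moment).  Aspect-ratio
change is deformed minus undeformed, per pair.

The effective scalar is the von Mises form on principal values, applied
identically to Cauchy stress and Green–Lagrange strain; the (2/3)-scaled
"effective strain" convention is *not* used.  Cell/ECM strain ratios are
invariant to that scale choice.  Maximum shear strain is the tensorial
(p₁ − p₃)/2, verified against brute-force maximization over sampled plane
orientations.  Volume averages weight by deformed element volumes.

## Summary analyses

Through-origin least squares (slope Σxy/Σx², SSR about the fitted line)
relates micro metrics to the macro effective strain of the driving element,
globally and per cell id (min/avg/max of the per-cell slopes).  Quartile
summaries use linear interpolation between order statistics (numpy's
`linear` method) — a convention choice, stated because quartile definitions
differ.

The material sensitivity protocol loads the eleven-cell construct with a
10 % nominal compression and volume-preserving lateral expansion
(F = diag(0.9^−½, 0.9^−½, 0.9)) under three tables: reference, reference
uniformly scaled ×10, and reference with the PCM's c₁ divided by 10.
Two points deserve emphasis.  First, uniform scaling of *all* stiffness
constants leaves a displacement-driven hyperelastic solution exactly
unchanged (stresses scale, strains do not) — the measured ratio change of
~1e−8 is pure solver tolerance, so this case is a consistency check rather
than a discovery.  Second, "PCM stiffness ÷ 10" scales c₁ (and c₂) while
keeping the PCM bulk modulus: the reference PCM is highly compressible
(K < 2c₁, ν ≈ 0.05), and softening its shear response alone turns it into a
compliant shear-isolating shell that measurably lowers cell effective
strain (−13 % to −18 % across the eleven cells at r = 30).  Scaling K down
with c₁ keeps the shell compressible and reverses the effect — a nested
Eshelby estimate shows the same sign — so the two readings of "stiffness"
are physically distinct, and the shear-only one is implemented.

## Synthetic fixtures: what passing tests show

No public deposition of the original joint-scale solution exists, so the
fixtures module generates hex-slab macro states from closed-form maps
(affine, volume-preserving uniaxial, simple shear, pure bending, and
compositions) whose exact F field is the oracle.  These validate the
extraction, filtering, batching and regression machinery end to end, and
the affine cases validate the full macro→micro→metrics chain because
affine fields make every stage's exact answer known.

What they do not emulate: contact-driven strain concentrations, anatomical
geometry, macro-element distortion, and the heterogeneous mix of
compression/shear states a real joint produces.  Trend results (strain
amplification of cells over ECM; strain shielding in the eleven-cell
construct, tested over five compressive load levels) are therefore
structural properties of the micro model, demonstrated under clean loading
— not predictions of in-vivo magnitudes.  Regression slopes and SSRs from
fixture batches characterize the pipeline, not cartilage.

## Numerical problem sizes used in the shipped tests

Unit tests run on 2³–4³ blocks and micro resolutions 12–24.  The trend and
sensitivity studies run at micro resolution 30 (27k elements, ~90k DOF,
five compressive levels for two constructs; three material cases), chosen
as the coarsest resolution at which the PCM shell is at least one voxel
thick everywhere and the per-cell metrics are stable; the shape-analysis
reproduction uses 40–48 voxels across the sphere diameter.  The
mesh-convergence logic mirrors a coarse-to-fine comparison rather than
fixing one "converged" mesh.

## Known limitations

* One-way coupling only; no homogenization feedback to the macro scale, no
  second-order (gradient-of-F) boundary terms.
* Elastic, isotropic micro constituents; no fibers, poroelasticity or
  viscoelasticity; single time-point transfer.
* Voxel meshing under-resolves the 3.3 μm PCM below r ≈ 30 (one voxel) and
  needs r ≈ 60 for two voxels; PCM-sensitive quantities at coarse r carry a
  discretization bias of a few percent, and one poorly-shelled cell at
  r = 20 can even flip the sign of a small per-cell effect.
* At the reference ECM compressibility (K/c₁ ≈ 49), the exact uniaxial
  response in tension at λ = 1.2 sits ≈ 2.4 % from the incompressible
  closed form; this is a property of the material constants, not solver
  error (the solver matches the compressible semi-analytic solution to
  < 0.5 %).
* The inertia-based shape fit lumps element volumes at centroids; its
  voxelization error largely cancels in undeformed/deformed differences
  (the sphere-elongation benchmark is exact to 4 decimals at r = 40) but
  per-cell aspect ratios at coarse r are noisy at the percent level.
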