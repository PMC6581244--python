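# Methods

This note documents the models, parameter choices and numerics behind
`infantfem`, and what the synthetic test bed does and does not show about
real paediatric data.

## Synthetic femur phantom

The phantom stands in for segmented, co-registered CT/MRI data, which for
post-mortem infant imaging cannot be redistributed. It reproduces the
*statistical and geometric structure the analysis consumes* — region
labels, a CT-like intensity field, landmarks — not CT physics.

Geometry is deliberately minimal: a straight hollow cylinder (cortical
shell around a trabecular core) and an ellipsoidal proximal epiphysis
attached along a neck axis tilted by (180° − neck-shaft angle) towards
medial and rotated by the anteversion angle, overlapping the metaphysis by
2 mm so the regions are voxel-connected. The distal epiphysis is not
generated; labels end at the distal shaft. Published overall dimensions
constrain only lengths, volumes and the epiphyseal cross-sectional area,
so for each preset the ellipsoid semi-axes are fixed analytically (axial
semi-axis a = 3V/4A, transverse b = c from πbc = A) and the shaft radius
was calibrated once so the voxelised total volume lands on the reference
value (4 mo: outer radius 6.26 mm, cortex 2.5 mm; 7 mo: 8.48 mm, cortex
3 mm — plausible infant values; nothing downstream depends on them beyond
the volume targets). Neck-shaft angle 155° and anteversion 10° are typical
infant values and mainly serve to make the geometry non-axisymmetric.

Intensities: uniform class values (cortical 2200 HU, trabecular 500 HU,
epiphysis 125/80 HU for the 4/7-month presets), a linear ramp of width
3 mm across the metaphyseal interface plane emulating progressive
mineralisation, and i.i.d. Gaussian noise (default SD 30 HU, seeded).
The two epiphysis HU values were chosen so the default calibration law
returns ossifying-region moduli of ≈0.60 and ≈0.46 GPa respectively,
the documented stiffness difference between the two developmental stages.
Voxel spacing defaults to 1 mm; the generator rejects spacings that put
fewer than two voxels across the cortex.

What passing phantom-based tests does **not** show: robustness to
segmentation error, partial-volume effects, beam hardening, or real
paediatric anatomy (curvature, trochanter, growth plate shape).

## Meshing

No tetrahedral mesh generator is assumed; meshing is structured: labels
are resampled onto a grid at the requested edge length, each occupied cell
is split into six tetrahedra (Kuhn split, consistent shared diagonals) and
the mesh is promoted to quadratic with one shared mid-edge node per edge.
Cells are ranked by tissue occupancy and the inclusion cutoff is placed
where the meshed volume equals the labelled voxel volume; a plain ≥50 %
majority vote was measured to inflate small cross-sections by up to ~10 %
at coarse cell-to-feature ratios, while the ranked cutoff is
volume-consistent by construction (typically within 0.1 %). Element
regions come from the cell's majority label, ties broken towards the
ossifying region (conservative for the failure mask). The boundary is a
staircase: surface strain fields carry local corner concentrations, which
is why verification problems use the smooth structured cylinder/box
meshes and why capacity comparisons are made between identically meshed
models.

Default target edge: 2.5 mm (4 mo, ≈5 000 elements ≈26 000 DOF) and
2.5–3.0 mm (7 mo, ≈7 000–12 000 elements). These sizes keep a full
four-load-case pipeline around a minute on one CPU while the torsion
capacity changes by <2 % between 2.0 and 3.0 mm.

## Material mapping

HU → density (ρ = 0.1 + 0.0008·HU g/cm³) → modulus (E = 6850·ρ^1.49 MPa,
clamped to [50, 18000] MPa). The power-law form and exponent follow the
common density–modulus convention; the coefficients are calibration
constants of the phantom (they are what make the preset HU classes land on
the documented modulus ranges, cortical ≈16–18 GPa, ossifying
≈0.46–0.60 GPa) and live in configuration for use with differently scaled
inputs. Per element, the law is applied pointwise at 32 sampling points
(a degree-2 rule on a 1:8 subdivision of the element) with mask-aware
trilinear interpolation — background voxels get zero interpolation weight,
so boundary elements average only over labelled tissue — and then
volume-averaged ("pointwise-then-average"). Averaging HU first is
available behind a flag for sensitivity studies only.

The ossifying region is porohyperelastic. The compressible Neo-Hookean
parameters follow the standard identification μ = 2C10, κ = 2/D1, i.e.
C10 = E/(4(1+ν)) and D1 = 6(1−2ν)/E with ν = 0.20, applied to each
element's own image-derived modulus. The permeability is stored as
printed, 0.00455 m⁴/(N·s); note this *is* a standard quantity — the Darcy
mobility k/μ in m²/(Pa·s) — and is converted to mm⁴/(N·s) inside the
poroelastic solver. Void ratio 4.50 is carried as metadata (the linear
u–p formulation with incompressible constituents does not consume it).

## Solvers

TET10 elements, 4-point degree-2 quadrature (5-point degree-3 available).
Small-strain mode assembles K = Σ BᵀDB vectorised over elements and uses
SuperLU with the symmetric-friendly `MMD_AT_PLUS_A` ordering; one
factorisation is reused across load cases with identical constraints.
Dirichlet constraints are eliminated; rigid kinematic couplings
(u = u₀ + θ×r to a 6-DOF virtual point) are implemented by a sparse
congruence transform and carry applied wrenches — they serve both load
application through a quasi-rigid patch and the rigid-epiphysis oracle.

Point loads are never applied at single nodes (singular in elasticity):
forces/moments are spread over the nodes within 3 mm of Point 1 as the
minimum-norm statically equivalent force set (an equality-constrained
least-squares problem solved in closed form; the achieved resultant is
verified to 1e-9). The distal fixation clamps a full 6 mm cross-section
slab around Point 2 rather than a small sphere, avoiding an artificial
interior stress singularity at the constraint.

Hyperelastic mode is total-Lagrangian Newton on the Neo-Hookean energy
(Cauchy stress σ = (2C10/J)·dev(B̄) + (2/D1)(J−1)I, pulled back to the
first Piola stress), with the consistent tangent obtained by central
finite differencing of the analytic element internal forces
(step 1e-7·max(1, |u|); 60 vectorised passes per iteration). Convergence:
residual ≤ 1e-8 of the external force norm, 30 iterations maximum,
non-convergence flagged with the partial result retained. Strains are
reported as Green–Lagrange in this mode, small strain otherwise; both are
element volume-averages over quadrature points (a deliberate, documented
difference from nodal-extrapolated contour extrema).

Poroelastic mode is linear Biot u–p (quadratic displacements, linear
corner-node pressures — a Taylor-Hood-type pair), incompressible
constituents, backward Euler in time with geometric step growth; the
undrained instant is obtained from the Δt = 0 saddle system. The Terzaghi
column benchmark (32 elements through the depth, ≈320 steps) matches the
series solution within 0.7 % over T ∈ [0.05, 1.5] and reaches the drained
solution at T = 8 to 1e-6; the boundary layer at the drained face is
resolution-limited at the undrained instant, so the incompressibility
check is evaluated over the deeper 80 % of the column.

## Anatomical frame and load cases

The diaphyseal axis is the principal direction of the element-centroid
cloud; cross-sections at 25 % and 75 % of the diaphyseal axial extent
(shaft only — the sections are marked on the shaft, so the epiphysis is
excluded from "total length"; the alternative is a config choice) are cut
as exact element/plane intersection polygons, whose area centroids are
analytic. This makes the frame independent of how the volume was
tetrahedralised (a slab-membership centroid inherits a few-per-mil bias
from the asymmetric Kuhn split). X runs proximal→distal through the two
centroids, Y is the medial hint orthogonalised against X, Z = X×Y. For
imported meshes without generator metadata the user supplies the
medial/anterior hints.

## Failure criterion

Tensile limit 0.73 %, compressive 1.04 % — adult cortical-bone limits,
used as a proxy because no infant-specific limits exist; capacities should
be read comparatively, not as absolute paediatric tolerances. Only
diaphysis elements are assessed, and by default the one-element layer
touching the epiphysis is excluded so the (real, reported) interface
concentration does not set the shaft capacity; both choices are
criterion flags. In linearised mode the capacity is the closed-form
scaling of the probe load; in hyperelastic mode a bisection on the load
factor terminates when the bracket is within 0.5 %.

For the degenerate-epiphysis oracles, note that an infinitely stiff but
unanchored epiphysis is kinematically a *rigid section coupling* of the
interface (it may still translate/rotate), not a clamp to ground; the
rigid-limit oracle therefore couples the bone-only interface nodes to a
virtual point, which is the exact limit. The soft limit applies the load
on a diaphyseal section so that a vanishing-stiffness epiphysis carries
nothing and the interface becomes traction-free.

## Known limitations

Staircase surface (no boundary-conforming mesher); isotropic linear
elastic bone; single-load quasi-static cases only (no contact, impact or
multi-axial combinations); adult strain limits; phantom realism as noted
above. The moment-to-fail magnitudes depend on the phantom geometry and
calibration constants and are meaningful mainly in the with/without-
epiphysis comparison, which is the analysis' purpose.
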