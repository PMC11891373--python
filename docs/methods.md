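# Methods

`fnstab` studies how the placement of a Femoral Neck System (FNS) affects
the primary stability of a Pauwels type III (70°, shear-dominated) femoral
neck fracture. Because the original analysis was built on a single
patient's CT and a commercial solver, this package replaces both with
fully synthetic, analytically checkable counterparts: a parametric
surrogate femur and an in-package finite-element (FE) backend. The goal
is a reproducible pipeline whose every stage can be verified against
closed forms, not a patient-specific prediction.

## The placement grid

The standard placement inserts a 95 mm bolt along the femoral neck axis
with a fixed 10 mm preslide. Sixteen variants each change exactly one
factor:

* bolt length 90, 85, 80, 75 mm;
* entry offset along the shaft axis +5, −5, −10, −15 mm (positive =
  superior);
* axis–bolt angle α in the AP view +3, −3, −6, −9° (positive = outward);
* axis–bolt angle β in the lateral view +10, +5, −5, −10° (positive =
  anterior).

Rotations pivot at the lateral entry point, so the plate position is
invariant under ABA changes, matching how a surgeon re-angulates through
the same cortical window. The two rotations are applied in an
orthonormal frame built from the neck direction and the coronal (AP
view) normal re-orthogonalized against it; with this construction the
AP-projected angle equals α and the out-of-coronal elevation equals β
exactly, even for an anteverted neck, and `aba_angles` inverts the map
to machine precision.

## Surrogate femur

The geometry is a union of primitives — spherical head (r = 24 mm),
capsule neck (r = 13 mm, neck–shaft angle 130°, anteversion 15°), and a
cylindrical shaft (outer r = 15 mm, length 120 mm; the model is the
proximal femur only, fully fixed at its distal cut face). Defaults are
standard adult anatomy; every geometric property (shell volume
fractions, drilled-channel volumes, entry points, tip–subchondral
distances) has a closed form or a Monte-Carlo oracle the tests compare
against.

Meshing is voxel-based: each grid cell splits into the six Kuhn
tetrahedra, which tile conformally; elements are classified at their
centroids. A quality gate (positive volumes, scaled-volume floor)
rejects degenerate meshes rather than passing them downstream. Thin
implant parts (antirotation screw, locking screw, plate shell) get a
minimum effective thickness of about one cell so they stay resolved on
coarse grids.

The Hounsfield field is drawn per element from N(1500, 100²) in the
cortical shell and N(300, 50²) in cancellous bone — chosen so the
density law spans both sides of the 1.2 g/cm³ elasticity branch — using
a counter-based hash of the element's absolute grid address. This makes
the field bit-reproducible and stable under re-meshing: an element that
exists before and after implant embedding keeps its HU value. The
articular head carries no cortical shell: the physical subchondral plate
is sub-millimetre, far below any element size this package runs at, so
head elements are cancellous throughout.

What the surrogate does **not** emulate: patient-specific cortical
thickness gradients, the principal compressive trabecular column,
femoral curvature and the greater trochanter, and a full-length shaft.
Passing tests therefore demonstrate correctness of the pipeline and the
qualitative mechanics of a homogeneous construct — not agreement with
any patient's absolute stiffness or stress values (see Limitations).

## Fracture and implant

The 70° Pauwels plane is the horizontal plane through the head center
tilted about the anterior axis and shifted 15 mm along its own normal so
it crosses the mid neck. The cut reassigns head/neck elements by plane
side (shaft elements are never reassigned, so the infinite plane cannot
claim the medial shaft wall), snaps near-plane bone nodes onto the plane
(reverting any snap that would degenerate an element; total volume change
is asserted below 0.5 %), and duplicates the shared nodes into paired
penalty-contact nodes.

The implant embeds by re-meshing the same grid with the implant
primitives added: bone cells overlapped by the bolt (r = 5 mm),
antirotation screw (r = 2 mm, 8.5 mm superior and parallel), plate
(cylindrical shell sector on the lateral cortex), or locking screw
become implant elements — the removed bone volume is the drilling loss
and is checked against a Monte-Carlo oracle within 5 %. The cut is
applied after embedding so the implant stays continuous across the
plane. Interfaces are realized as duplicated-node penalty pairs at:
fracture (μ = 0.46), bolt–bone (μ = 0.3), plate–bolt and
plate–antirotation-screw (μ = 0.2), and plate–bone (μ = 0.3; the plate
presses on the cortex but is anchored only through the locking screw).
The antirotation screw and locking screw are bonded to bone (merged
nodes). The bolt's preslide means its tip sits `bolt_length − 10 mm`
along the axis from the entry point.

## Load case and solver

Single-leg stance: 2100 N (3 × 70 kg with g = 10 m/s², making the
printed value exact) applied as an area-weighted traction over a small
patch (default radius 8 mm) of the head surface around the load axis —
a patch, not a point, to avoid singular stresses. The direction is −Z
tilted 8° posteriorly in the sagittal plane, then 13° in the coronal
plane. The coronal tilt defaults to lateral, as the source load
specification states; because typical hip-contact forces point medially,
`LoadCase(coronal_sense=-1)` flips it, and absolute outputs differ
substantially between the two senses. A 224 N preload is applied as
equal-and-opposite axial forces at the two ends of the antirotation
screw. The distal shaft face is fully fixed.

The FE backend assembles isotropic linear elasticity on 4-node
(constant-strain) or 10-node (quadratic, 4-point Gauss) tetrahedra;
quadratic meshes are generated on the fly by promoting unique edges, so
boundary conditions and contact pairs defined on corner nodes carry
over (midside components are additionally fixed whenever both edge
corners are fixed). The linear solve is a sparse LU factorization; the
equilibrium residual must fall below 1e−8 or the solve raises.

Frictional interfaces are penalty springs (default 5·10³ N/mm³ normal
and tangential — roughly ten times the bone modulus over an element
edge, keeping interface compliance small against bulk compliance)
resolved by a relaxed secant iteration: open pairs (positive gap) drop
their springs; pairs whose trial tangential traction exceeds μ·σₙ get an
effective tangential stiffness μ·σₙ/|slip| that caps the traction at the
Coulomb limit. Stiffness updates are under-relaxed (ω = 0.6) and the
iteration stops when the L2 relative change of the interface traction
vector falls below 1e−4 (max 100 iterations, raising on
non-convergence). The 1e−4 threshold was chosen because the fixed point
contracts linearly (rate ≈ 0.85 on construct problems), so each extra
decade costs ~15 refactorized solves, while the stability metrics move
by less than 0.1 % between 1e−4 and 1e−6 on spot checks. With
`cap_model="linear"` every spring stays closed and uncapped, making the
operator exactly linear — the configuration used by the
linearity/scaling property tests.

Verification oracles: an axial rod reproduces EA/L to round-off (roller
conditions make the constant-stress state exact); a 10×10×100 mm
cantilever with quadratic elements at 2.5 mm reproduces PL³/3EI within
0.7 % (the remaining difference is genuine shear deflection plus
discretization); a two-block pair with a prescribed 0.5 mm opening
reports exactly that gap through the traction/gap extraction path; and
external work equals twice the strain energy on bonded problems to 1e−8.

## Stability metrics

* **Stiffness** — load magnitude over the displacement of the load
  reference point projected on the load direction. The reference point
  is the area-weighted centroid of the load patch (a patch needs a
  representative point; the published definition divides by the
  displacement at the load application point).
* **MIVS** — maximum von Mises stress over implant elements (Gauss-point
  maximum for quadratic elements), with location.
* **MISS** — maximum tangential traction magnitude over the fracture
  pairs.
* **MIG** — maximum positive normal opening over the fracture pairs;
  compressed pairs contribute zero. Measured along the plane normal (the
  fragment-separation direction); total relative displacement is
  available from the pair kinematics for sensitivity checks.

Each maximum equals an exhaustive scan in tests; under pure load scaling
(caps disabled, preload scaled with the load) stiffness is invariant and
the other three scale linearly.

## Reduced-order backend

A beam-and-spring surrogate for fast sweeps: the construct is a series
pair of a head-support spring k_head = E_bone·A_eff/(d_tip + d₀) —
softening as the bolt tip retreats from the subchondral bone, the
tip–apex effect — and an implant bending spring k_imp = 3·E_imp·I/ arm³
whose lever arm grows with inferior offset and axis eccentricity (the
lever-hinge picture of varus collapse), times a load–axis misalignment
penalty. Stiffness is homogeneous of degree one in the two moduli by
construction. The stress and gap proxies are the corresponding beam
bending/shear/deflection expressions. The calibration constants
(A_eff = 300 mm², base arm 20 mm, d₀ = 5 mm) are order-of-magnitude
choices documented in `ReducedOrderParams`; the backend is used for
rank-order comparisons, never absolute values.

## Entropy-weight ranking

The 17×4 metric table is min–max normalized with stiffness as a benefit
and MIVS/MISS/MIG as costs (higher stiffness and lower stresses/gap mean
a more stable fixation). Column weights come from Shannon entropy:
p_ij = z_ij/Σz_ij, e_j = −(1/ln n)·Σ p ln p (0·ln 0 := 0),
d_j = 1 − e_j, w_j = d_j/Σd. A constant column carries no information
(e = 1, w = 0, logged); a matrix with no informative column raises.
Composite scores are the weighted sums of the normalized matrix, in
[0, 1], ranked descending with ties broken by lower MIG, then higher
stiffness, then label. The normalization and weighted-sum recipe are the
standard entropy-weight construction; applied to the published utility
column (0.037, 0.029, 0.054, 0.18) it reproduces the published weights
(60.0 % vs 60.04 % for MIG) within rounding of the printed inputs, which
is the package's evidence that this recipe matches the one used at the
source. Every intermediate (normalized matrix, p, e, d, w, scores) is
exported so alternative recipes can be compared.

The synthetic decision-matrix generator plants a weight vector by
shaping each column's normalized profile as u^c on a uniform grid with
the exponent increasing in the planted weight: more skew, lower entropy,
higher weight. Equal plants give exactly equal recovered weights; as
noise → 0 the recovered weight ordering matches the planted ordering
(10/10 seeds in the acceptance run).

## Printed-value audit

The source study prints absolute metric values and percent changes
against the standard model, but not the standard model's MIVS, MISS or
MIG. The audit inverts one percent statement per metric to recover the
baseline (e.g. 160.3 MPa at +136.4 % ⇒ 67.81 MPa standard MIVS;
1.25 mm at +5 % ⇒ 1.1905 mm standard MIG) and recomputes every other
statement from its printed absolute value. All twenty shipped records
agree within 0.081 percentage points — inside the 0.15 pp bound implied
by one-decimal rounding — so the published arithmetic is fully
self-consistent and the recovered baselines are trustworthy.

## Problem sizes

The surrogate's default element size is 1.5 mm with quadratic
tetrahedra, mirroring the converged configuration of the reference
analysis. The test suite and the acceptance script run deliberately
coarse desk-scale configurations — 5 mm and 4 mm linear tetrahedra
(~7 000–15 000 elements per construct, seconds to tens of seconds per
solve) — which resolve the construct-level load paths but not local
stress concentrations; the verification fixtures, not the construct
runs, establish discretization accuracy.

## Known limitations

* Absolute construct outputs do not, and are not expected to, match the
  patient-specific published values: the surrogate geometry, its
  homogeneous two-level density field, and the proximal-only shaft all
  differ from a CT-derived femur. The package's quantitative claims are
  the closed-form verifications, the published-arithmetic audit, and the
  entropy-weight reproduction; construct results are qualitative.
* **Directional trends.** FE stiffness falls monotonically as the bolt
  shortens (95 → 75 mm), as published, and the reduced-order backend
  reproduces both the length and inferior-offset trends. The FE
  inferior-offset trend on this surrogate, however, runs opposite to the
  published finding: moving the titanium bolt inferiorly shifts it into
  the compressive calcar-side load path of a homogeneous neck, and that
  reinforcement outweighs the lever-arm softening (MIG still worsens
  monotonically below −5 mm, and implant stress falls rather than
  rising). Reproducing the published stiffness collapse at −15 mm
  appears to require features this surrogate deliberately lacks —
  CT-mapped density structure and near-breach tip mechanics. The
  corresponding check is left failing rather than weakened; the
  acceptance report states the measured trend fractions.
* Friction is small-slip penalty Coulomb around a linear solve, not
  large-deformation contact; penalties admit ~1e−4 mm-scale
  interpenetration at working tractions.
* The bolt–plate telescoping is frictional but the locking-screw–plate
  and screw–bone connections are fully bonded; thread mechanics, cyclic
  loading and bone yielding are out of scope.
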