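# Methods

## Model and assumptions

The package models a layered tissue column — epidermis, dermis, adipose,
skeletal muscle, bone — loaded by a rigid circular sensor of radius
a = 5 mm on the skin surface. The governing assumptions:

* **Quasi-static hyperelasticity.** All soft layers share a compressible
  Neo-Hookean energy `W = μ/2(I₁−3) − μ ln J + λ/2(ln J)²` with ν = 0.48.
  A normalized Prony relaxation `g(t) = 1 − Σγᵢ(1−e^(−t/τᵢ))` is available
  per layer, but no published γ/τ values exist for these tissues here, so
  the default analysis is the instantaneous elastic response (g ≡ 1); the
  static "time" is purely a load-scaling parameter. Bone (and the sensor)
  are treated as linear elastic; at the ~10⁻³ strains bone experiences the
  Neo-Hookean evaluation is numerically identical, so one constitutive
  path serves both, with a flag marking linear materials as exempt from
  soft-tissue softening.
* **Axisymmetric geometry.** The circular load, layered planar geometry
  and radially constrained far boundary make the problem axisymmetric to
  good approximation; the 120 mm × 120 mm surface plane maps to a disc of
  radius 60 mm (the half-width is preserved). z = 0 at the surface,
  increasing with depth; units mm / kPa throughout, so forces are kPa·mm²
  with no conversion constants.
* **Boundary conditions.** Bone base fully fixed; outer radius and
  symmetry axis roller-constrained (zero radial motion); layer interfaces
  conforming (tie / no-slip). A "confined" variant (rollers everywhere,
  base vertical fix) exists for the uniaxial-strain benchmark.
* **Loading.** Default library mode is a uniform follower traction over
  r ≤ a. The study/reproduction mode is a frictionless rigid punch: the
  surface nodes under the sensor are displaced vertically (radial sliding
  free) by displacement continuation until the punch reaction equals
  p·πa², which is how a stiff sensor (E = 1300 kPa, far stiffer than any
  soft layer at the relevant scale) actually delivers pressure. The
  traction idealization lets the stiff epidermis bulge outward and
  under-transmits stress to depth; the punch was therefore chosen for the
  comparative study.

## Parameters

Layer defaults (thickness mm / E kPa, ν = 0.48 soft, 0.33 bone):

| layer     | model1 t | model2 t | E    |
|-----------|----------|----------|------|
| epidermis | 0.1      | 0.07     | 1500 |
| dermis    | 1.5      | 0.8      | 35   |
| adipose   | 4.4      | 3.0      | 2    |
| muscle    | 6.6      | 6.6      | 21   |
| bone      | 5.0      | 5.0      | 6480 |

The source table for these values is typographically run together, and two
readings of the muscle row are arithmetically possible (shared E = 21, or
E = 2 / 1 per model). We ship E = 21 kPa shared: the reference element
counts imply a shared muscle geometry, 21 kPa is mid-range for skeletal
muscle in the measurement literature (1–2 kPa is not), and only this
reading yields the documented adipose-dominant strain depth profile
(≈ 1 : 1.2 : 6 : 1.2 across epidermis : dermis : adipose : muscle); with a
1–2 kPa muscle the strain maximum moves into muscle, contradicting the
profile the models are meant to exhibit. Every value is a config key, so
the parse is non-binding. Under this parse the two models differ in layer
thicknesses only.

Load cases: 2, 6, 8, 10 kPa. Softened variants scale all soft-layer E by
0.9 / 0.8; bone untouched. Region of interest: r ≤ 15 mm through the four
soft layers.

## Discretization and numerics

* 6-node quadratic triangles on a structured grid, graded radially
  (uniform a/n_patch spacing under the patch, geometric growth outward,
  with the patch edge and the ROI radius imposed exactly as grid lines) and
  at least three element layers through every tissue, including the
  0.07-mm epidermis. Resolutions: coarse (~440 elements), medium (~950),
  fine (~1900); element ring volumes are exact (area × 2π r̄) and sum to
  the analytic slab volumes to machine precision.
* Total-Lagrangian kinematics with the packed axisymmetric deformation
  gradient (F_rR, F_rZ, F_zR, F_zZ, 1 + u_r/R); analytic Neo-Hookean
  tangent; 3-point Gauss quadrature (rank-sufficient, and the mild
  under-integration relieves volumetric stiffness at ν = 0.48 — the
  ROI-averaged J stays within [0.95, 1.05] at 10 kPa, verified in the
  suite). Sparse LU on the assembled system.
* Newton with a consistent treatment of prescribed-displacement
  increments (the K_fc·Δu_c coupling enters the linear solve, so the
  0.03-mm epidermis elements are never handed an inverted trial state) and
  an inversion-guarding damped step. Convergence at relative force
  residual 1e-8 against the external-force/reaction norm, with a
  stagnation floor of 1e-6 relative: the layered stiffness spans nearly
  seven orders of magnitude (6480 kPa bone and a 1500 kPa film 0.03 mm
  thick against 2 kPa adipose), which puts the roundoff floor of the
  residual around 1e-8–1e-7 relative on some increments.
* Adaptive load stepping per the configured schedule (initial 0.05 of the
  step, halving on failure, ×1.5 growth after two fast increments, floor
  1e-6, at most 1000 increments). The rigid punch uses depth continuation
  with a secant loop on the reaction–depth curve (tolerance 0.1 % on the
  target reaction), warm-starting every depth from the previous state.
* Postprocessing: per-Gauss-point Cauchy stress σ = J⁻¹PFᵀ and Hencky
  strain ½ ln(FᵀF) (closed-form 2×2 eigendecomposition plus the hoop
  stretch), volume-averaged per element.

Verification, all enforced in the test suite: patch test (constant-strain
Dirichlet data reproduced to 1e-8), reactions balancing the applied load to
1e-6 relative, confined compression against a scalar root-finding oracle
(machine precision at coarse resolution; tolerance 0.5 %), low-load
circular pressure on a deep homogeneous domain against
w₀ = 2pa(1−ν²)/E (within 10 %, finite-domain limited), external work vs
stored energy within 1 %, and medium→fine ROI-mean drift < 5 % (measured
≈ 0.3 %).

## Exposure pipeline

Reference thresholds are the volume-weighted 75th percentiles of each
tissue's ROI-restricted distribution in Model 1 at baseline stiffness, per
pressure and per quantity (stress, strain). The percentile convention is
linear interpolation of value against cumulative volume fraction
(right-continuous at exact hits), which reduces to the standard empirical
quantile for equal volumes; it is documented so results are
bit-reproducible. Exceedance curves are exact step functions of the
volume-weighted order statistics, so AUC integrals are exact
(`auc(·, 0)` equals the volume-weighted mean identically).

Two published exposure definitions disagree — an AUC ratio
(`100·AUC_from_threshold/AUC_total`) versus "percentage of tissue volume
above the threshold". Both are computed and reported in every row; the
volume-fraction form is the default comparison because the figure captions
define the plotted quantity that way. Per-layer percentages use the
tissue's whole-layer volume as denominator (the layer-specific captions'
reading), with thresholds from the ROI; the "total" rows accumulate the
four per-layer percentages (the stacked-bar reading) and also carry a
volume-weighted alternative.

For cross-condition comparisons the per-tissue thresholds derived at the
highest studied pressure (10 kPa) are applied to every pressure. A
threshold re-matched at each pressure makes the metric scale-invariant —
Model 1's own exposure would then be essentially pressure-independent,
which contradicts the defining observation that exposure is negligible at
2–8 kPa and appreciable only at 10 kPa. The full per-pressure threshold
table is still produced and exportable.

Two consequences of these definitions are worth knowing. First, the
reference model pins itself: at the threshold-defining condition exactly
25 % of each tissue's ROI volume exceeds its own threshold, so Model 1
baseline per-layer exposure is bounded below by
25 % × V_ROI/V_layer ≈ 1.56 % (domain radius 60 mm), and the four-layer
total by ≈ 6.25 %. Second, under load control, uniformly softening all
soft layers increases strain exposure but slightly *decreases* stress
exposure: the contact deepens and widens, spreading load and lowering peak
stresses against the fixed thresholds. Both behaviours are intrinsic to
the metric definitions, not numerical artifacts.

## Synthetic fixtures

`benchmarks.generate_field` emits seeded per-element tables in the same
CSV schema the solver writes (lognormal by default — positive and
right-skewed like indentation fields; uniform and gamma available), so the
exposure pipeline is exercised without the solver, against closed forms
(uniform-distribution exposure 6.25 % AUC / 25 % volume at 0.75·max;
lognormal tails). The two-cohort fixture scales the deep-layer strain
distributions of one cohort multiplicatively, giving an analytically known
exposure contrast. These fixtures have no spatial correlation structure:
passing pipeline tests demonstrates correct exposure arithmetic, not
realism of any particular stress field.

## Problem sizes

The shipped study and reproduction script run on the medium mesh
(~950 elements, ~4 000 unknowns per model; each 10-kPa solve takes a few
seconds on one CPU), where the ROI means sit within ~0.3 % of the fine
mesh. The published reference computation used ~3×10⁵ three-dimensional
hybrid tetrahedra; the axisymmetric medium mesh is the package's own
choice of a resolution whose discretization error is far below the
idealization differences that dominate any comparison.

## Known limitations

* Axisymmetric idealization: no square-domain corner effects, no
  off-center or shear loading, no patient-specific geometry.
* Isotropic Neo-Hookean only; no fiber anisotropy, plasticity, or damage.
* Viscoelasticity is parameterizable but not exercised by default (no
  published constants); perfusion, ischemia and thermal effects are out of
  scope.
* The frictionless punch prescribes a flat contact footprint over r ≤ a;
  partial lift-off at the patch edge is not modelled (the deformable-sensor
  contact problem is deliberately avoided).
* Exposure percentages inherit the definitional ambiguities discussed
  above; both variants are reported so downstream users can choose
  explicitly.
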