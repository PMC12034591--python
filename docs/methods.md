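# Methods

`mammofem` converts a prone-position breast model to the supine position
for image-guided breast-cancer surgery. Preoperative MR images are taken
prone; surgery happens supine, and the breast — a soft, partly fluid-like
organ — deforms by centimetres between the two postures. The package
implements a semi-fluid finite-element representation of that deformation
together with an observation-driven registration that fits the model to
supine CT-derived surface data, and the full synthetic evaluation
protocol around it.

## Mechanical model

The displacement `u` of the prone tetrahedral model satisfies the linear
balance

    K u = F_g + F_p + F_a + B α

* `K` — global stiffness of 4-node constant-strain tetrahedra with an
  isotropic Hooke law. Linear (small-strain) elasticity is used
  throughout; a Neo-Hookean large-strain model would represent the
  centimetre-scale deformation more faithfully but is out of scope here.
* `F_g` — consistent gravity body load, `ρ V g` per element lumped V/4
  per node.
* `F_p` — penalty contact forces against the chest wall (below).
* `F_a` — anchoring constraint forces along the inframammary fold
  (below).
* `B α` — an observation-driven term: a linear combination of
  deformation bases fit to the supine observation (below).

**Tissue layering (semi-fluidity).** Per-element Young's moduli encode
the anatomy: skin 4 kPa; gland 9.75 kPa; superficial adipose is bound to
the gland by the superficial fascial system and shares its 9.75 kPa; the
deep adipose layer within 15 mm of the chest wall is softened to the
cross-validated 0.83 kPa so it can shear almost freely — the "fluid" part
of semi-fluidity. The tumor is labeled but carries the gland stiffness
(no published tumor modulus is used). Poisson's ratio is 0.495
everywhere. Near-incompressibility causes volumetric locking in pure
displacement P1 tetrahedra; this is a known stiffness overestimate that
we accept and mitigate only by mesh resolution, not by a mixed
formulation.

**Units.** mm – kPa – mN internally (1 kPa·mm² = 1 mN); gravity loads
convert (kg/m³)(m/s²)(mm³) → mN via 1e-6. Tissue density defaults to
1000 kg/m³ (not specified in the source work; configurable).

**Gravity convention.** The prone model is imaged loaded by gravity
toward the anterior (+z); supine gravity points posterior (−z). Because
the linear model carries the prone pre-stress (no unloading step is
performed — a documented limitation), the net prone→supine load change is
2 g along −z, the default. A 1 g magnitude is selectable.

**Boundary conditions.** The chest midline is fixed (homogeneous
Dirichlet, imposed by row/column elimination for conditioning). On the
hemisphere phantom, which has no sternum, the medial edge of the chest
base (nodes within 5 mm of the x = −R plane) stands in for the midline
strip.

## Contact with the chest wall

The supine chest wall is a second-order surface fitted to the chest-wall
point cloud. We use an explicit height field
`z' = c₁x'² + c₂y'² + c₃x'y' + c₄x' + c₅y' + c₆` in the frame of the
cloud's best-fit plane, which avoids the trivial-solution ambiguity of a
general implicit quadric. Penetration of a chest-side node is measured by
vertical projection along the local z' axis (not a true closest-point
search); the approximation error of that choice is bounded in the tests
against a dense-sampling nearest-point oracle. Penetrating nodes receive
`f = w_p E_i` with `E_i` the penetration vector pointing out of the wall.

The penalty weight `w_p` has no published value. It is set by the rule
"smallest power of ten for which the equilibrium maximum penetration on
the default phantom falls below 0.5 mm", which yields `w_p = 100` in the
mN/mm system (10 leaves ≈3 mm of penetration; 1000 destabilizes the
fixed-point iteration). The rule is implemented in
`contact.calibrate_penalty_weight` and the weight is fully configurable.

**Solver.** The penalty is stiff relative to the soft tissue, so the
equilibrium is found by a semi-smooth active-set iteration: active chest
nodes contribute an implicit penalty stiffness `w_p n nᵀ` to the system
matrix while their tangential position on the quadric and the (small)
anchoring forces are lagged one iteration. Activation uses hysteresis
(activate at depth > 0, release below −0.05 mm) to stop marginal nodes
from flapping the active set, and updates after the first are
under-relaxed (θ = 0.5). Factorizations are cached per active set.
Convergence is declared when the maximum nodal update falls below
0.01 mm with an unchanged active set.

## Anchoring structure

The deep fascia loosely tethers the breast along the inframammary fold
from mid-chest to axilla. It is modeled as a root point (the projection
of the nipple onto the chest wall along gravity) plus an ordered chain of
endpoint nodes on the fold; on the phantom the chain is the inferior half
of the base rim. Each endpoint i receives two tension-only forces, both
directed along the root-to-endpoint vector `q_i`:

* root tether, active when `|q_i| ≥ u⁰_i`:
  `w_a (|q_i| − u⁰_i)/(u⁰_i |q_i|) q_i`;
* neighbor coupling for each adjacent endpoint j, active when
  `|s_ij| ≥ |s⁰_ij|`: `w_a (|s_ij| − |s⁰_ij|)/(|s⁰_ij| |q_i|) q_i`.

Rest lengths are captured from the initial prone configuration. The
neighbor activation condition is implemented by symmetry with the root
tether (stretch-activated); the direction is `q_i` — toward the root —
reflecting the membranous character of the fascia. No activation
threshold beyond the rest length is applied (none is quantified). The
weight `w_a` defaults to the cross-validated 1e-4. In the mm–kPa–mN
system this makes the anchoring forces small relative to gravity loads
(the source work does not state its force normalization); the mechanism
is faithfully present and its weight is a grid-search dimension, but on
the phantoms its displacement effect is minor compared to chest-wall
release and deep-layer softening — consistent with the ablation outcome
that only chest fixation separates significantly.

## Observation-driven registration

Unknown loads are represented by deformation bases: for each of 70
control points (farthest-point sampled on the anterior surface) and each
axis, one basis column is the displacement response of the constrained
model to a unit point load there, normalized to unit maximum nodal
displacement (m = 210 columns). With `u(α) = u_base + B α`, the weights
minimize

    F(α) = Σ_skin ((S_i n̂)·p_i)² + Σ_chest ((S_i n̂)·p_i)²
         + Σ_fid |p_i|² + λ₁|α| + λ₂ Σ K_i

* Surface/chest terms: signed distance of each data point along the
  normal of its nearest model polygon (data-point → nearest-triangle
  correspondence; equidistant polygons break toward the lowest index).
* Fiducial term: plain Euclidean distance of the nipple and two vessel
  bifurcations (barycentrically advected material points).
* `λ₁|α|` is the Euclidean norm, not its square (λ₁ = 0.01); it enters
  the least-squares machinery through a smooth square-root residual row
  (ε = 1e-8 near zero).
* `K_i` is the sum over a surface node's incident triangles of the inner
  product between its area-weighted node normal and the triangle normal;
  the λ₂-weighted sum (λ₂ = 0.6) is added to F exactly as defined. Note
  that as defined K_i is maximal on flat regions, so the added term
  favors creases; it is retained as the stated objective. Its α-gradient
  is evaluated by vectorized forward differences; a constant shift keeps
  the residual-row square root real and cannot move the minimizer.

**Optimization.** A damped Gauss-Newton (Levenberg–Marquardt) iteration:
steps solve `(JᵀJ + μI)δ = −Jᵀr`, only cost-decreasing steps are
accepted, μ adapts by factors 3/4. The geometric Jacobian is the exact
linearization at the current closest-point correspondences, which are
refreshed at every evaluation. An outer fixed-point loop alternates
(i) the contact/anchoring equilibrium with the current `B α` held fixed,
(ii) correspondence refresh, and (iii) the LM update of α, stopping when
the surface displacement RMS changes by less than 0.05 mm (default ≤ 5
outer iterations). Accepted steps never increase F; an objective that
grows past 3× its best value aborts with the trace attached.

**Rigid pre-alignment.** The observation is first mapped into the model
frame by the least-squares proper rotation (Kabsch) on the three bony
landmarks (right/left sternoclavicular joints, lower sternum); collinear
triplets are rejected.

## Synthetic phantoms

No patient data ship with the package, so all evaluation runs on
phantoms: a hemisphere of configurable radius (default 50 mm) seated on a
cylindrically curved chest patch (height −c·x², c = 0.002/mm default).
Meshing samples a jittered interior lattice plus Fibonacci/Vogel surface
spirals and applies Delaunay triangulation (the domain is convex, so the
triangulation fills it); the lattice spacing is solved from the target
node count (default 1500, the published 820–2695 range). The hemisphere
is then sheared in z onto the chest surface — a volume-preserving map, so
the analytic hemisphere volume doubles as a meshing check (within 10%).
Labels are assigned by element centroid with priority tumor > skin >
deep adipose > gland > superficial adipose; the gland is a ball of
0.5 R centered at height 0.35 R, values chosen to give anatomically
ordered layers.

Supine observations are produced by the forward model itself (gravity +
contact + anchoring, no observation forces), sampling the deformed
anterior surface (area-weighted, default 2000 points) and the chest wall
(800 points), adding isotropic Gaussian noise (default 0.5 mm — CT
surface noise is not specified anywhere, so this is a package choice),
advecting fiducials and a 150-point tumor cloud barycentrically, and
optionally applying a small seeded rigid transform (≤5°, ≤12 mm) to
emulate the CT frame; the landmark triplet carries the transform so
registration can undo it. Ground truth (displacement field, supine tumor
cloud, noise-free fiducials) stays in the model frame.

What the phantoms do *not* emulate: real tissue heterogeneity and
boundary irregularity, MR/CT segmentation error, fascia strength
variation, breast-shape variety beyond radius/curvature/tumor-position
randomization, and pre-stressed prone states. Passing tests therefore
demonstrate the correctness and internal consistency of the machinery
and the direction of the mechanism effects — not clinical accuracy on
patients.

## Evaluation protocol

* **Metrics.** Tumor centroid alignment error (distance between cloud
  means) and the **directed** Hausdorff distance from the ground-truth
  supine tumor to the estimate — directed because it measures how far a
  true tumor point can lie from the planned excision margin. A
  symmetrized variant exists behind a flag, never default.
* **Ablation.** A: chest fixed, deep layer stiff (9.75 kPa), no
  anchoring; B: chest free, stiff, none; C: chest free, fluid (0.83
  kPa), none; proposed: chest free, fluid, anchoring on. Each differs
  from its neighbor by exactly one mechanism.
* **Grid search.** w_a ∈ {3e-5, 6e-5, 1.2e-4, 1.8e-4, 2.4e-4, 3e-4},
  E_deep ∈ {0.10, 0.50, 1.0, 1.5, 2.0} kPa; 9 cases split 6 train /
  3 validation in 3 folds (deterministic seeded round-robin); per fold
  the pair minimizing the mean training centroid error is selected and
  scored on the held-out cases; the "mean" optimal parameters are the
  arithmetic fold mean. The stiffness factorization and bases are reused
  across the w_a axis (they depend only on E_deep), collapsing the grid
  cost from 30 to 5 model preparations per case.
* **Statistics.** Pairwise two-sided variance F-tests (reported as a
  homogeneity pre-check, not gating), the Friedman test across the four
  paired method columns, then pairwise Wilcoxon signed-rank tests with
  Bonferroni multiplication capped at 1. Zero differences are dropped
  (standard signed-rank convention); an all-tied table short-circuits to
  Friedman p = 1 with no pairwise tests.

**Cohort conditions.** The synthetic cohort (9 cases) varies radius
44–58 mm, curvature 0.0012–0.0028 /mm, tumor position/size, and
generates each case's supine state with "true" semi-fluid parameters
cycling through values inside the search grids (w_a ∈ {6e-5, 1.2e-4,
1.8e-4}, E_deep ∈ {0.5, 1.0, 1.5} kPa), so the grid search has a
recoverable signal.

**Problem sizes.** The shipped tests and the acceptance script run the
cohort at ~700 nodes per phantom with 500/250-point clouds, 12 control
points, and shortened optimizer budgets; the default single-case
configuration runs at ~1500 nodes with the full 70 control points. These
sizes are the package's reproducibility settings; all quantities scale
with the same code paths.

## Numerical choices and degenerate inputs

* Linear solves: sparse LU (SuperLU), refactorized per active set and
  cached; solve residuals above 1e-8 relative raise.
* Degenerate tetrahedra (volume ≤ 1e-12 mm³) raise with the element
  index; phantom meshing drops boundary slivers below 1e-4 h³.
* Nearest-triangle queries use a KD-tree shortlist (k = 32) over
  triangle centroids with exact closest-point evaluation, falling back
  to a full scan for small surfaces; ties break to the lowest triangle
  index.
* A zero-length root-to-endpoint vector yields a zero anchoring force
  (no defined direction).
* Quadric fits require ≥ 6 points and a full-rank design; rank
  deficiency raises with the rank.
* All randomness flows through `numpy.random.default_rng` seeds; the CLI
  fans one global seed into fixed per-stage offsets, and a phantom is a
  pure (byte-identical) function of its parameters.

## Known limitations

Linear elasticity at centimetre deformations; P1 locking at ν = 0.495;
no gravity pre-stress unloading; vertical-projection penetration (exact
only where the wall is locally flat); homogeneous fascia strength; no
friction or left–right breast contact; the hemisphere phantom's fixed
midline strip is an analogue, not an anatomical sternum; and the
λ₂-smoothness term acts in the direction its definition implies (see
above), so regularization in practice leans on λ₁ and the basis span.
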