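# Methods

This note documents the models and procedures implemented in
`vertemorph`, the defaults and numerical choices, what the synthetic study
conditions do and do not emulate, and known limitations.

## Shape model

A shape is an ordered set of P corresponding 3-D points in millimetres;
correspondence across a family is positional (point i means the same
anatomical location in every individual).  Pose is removed by Generalized
Procrustes Alignment: shapes are aligned rigidly (rotation + translation,
no scaling — size is anatomy, not nuisance) to an evolving reference,
starting from the first shape in input order, re-centring the mean at the
origin each iteration to fix the translational gauge.  Convergence is
declared when the mean moves less than 1e-6 mm RMS per point (default),
with a hard cap of 100 iterations; non-convergence is flagged on the
result, never silently ignored.  The rotational gauge of the result is
the first shape's pose.  Rigid Procrustes itself is the SVD (Kabsch)
solution with a determinant sign correction so reflections are never
returned; configurations whose cross-covariance has fewer than two
significant singular values (collinear or coincident points) are
rejected.

PCA is computed in the dual (Gram-matrix) form: with n shapes and 3P
coordinates, the SVD of the centred n × 3P data matrix yields the same
nonzero eigenpairs as the 3P × 3P covariance at a fraction of the cost;
the equivalence is asserted against a dense-covariance oracle in the test
suite.  A model retains at most n − 1 modes.  Sampling is
`mean + Σ √dᵢ φᵢ wᵢ` with weights in SD units; projection is its exact
inverse on the retained subspace (zero-variance modes project to zero).

Model assessment:

- **Compactness**: cumulative explained-variance fraction.
- **Generalization**: deterministic leave-one-out — every shape left out
  once, reconstructed by orthogonal projection onto the model fitted on
  the rest.  The error metric is the root-mean-square per-point Euclidean
  distance (a mean-distance option exists); note this carries a √3 factor
  relative to per-coordinate noise.  A learning-curve variant (random
  training subsets, explicit seed) is available.
- **Specificity**: N random instances (default N = 1000, seeded; weights
  standard normal per mode, truncated to ±3 SD — the truncation mirrors
  the ±3 SD cohort convention) scored by distance to the most similar
  training shape.

Virtual cohorts are enumerated on an odometer grid over mode weights
(first mode slowest), 1-based IDs; the default grid of 5 modes × 7
integer levels (−3…3) yields 16 807 instances.

## Non-rigid registration and morphing

Template-to-target registration treats the moving template Y as centroids
of an isotropic Gaussian mixture fitted to the target X, with a uniform
outlier class of mass ω (default 0.10) over the target's bounding sphere
— the sphere, not the bounding box, so the formulation is exactly
equivariant under rigid motions.  The transform is
`T(y) = R(y + v(y)) + t` with `v = G W`, G the Gaussian kernel of width
β (motion-smoothing scale, default 8 mm) over the template points, and a
prior `(λ/2) tr(Wᵀ G W)` (deformation-magnitude weight λ, default 2).
EM alternates:

1. E-step responsibilities in log space (never NaN), outlier column
   included;
2. weighted-Procrustes update of (R, t) against the soft correspondence
   targets;
3. the coherent-field solve `(diag(P1) G + λσ² I) W = diag(P1)(X̂′ − Y)`
   in the rotated template frame;
4. the closed-form σ² update.

The deterministic EM point estimate stands in for posterior sampling of
the transform parameters (the posterior's mean/mode).  Iterations stop
when the negative log-posterior changes by less than the tolerance
(default 1e-15, i.e. effectively on the 1000-iteration cap or on σ²
collapse below 1e-12, which is a clean, flagged stop).  Identity-level
fits resolve to ~1e-5 mm at the collapse stop — far below any
mesh-relevant scale.  The objective decreases monotonically (tested).
Nyström / neighbour-search acceleration parameters are accepted for
config compatibility but computation is exact at the problem sizes this
package targets.

**Rigid registration** is the infinite-stiffness limit (λ = 1e9), which
reduces the M-step to correspondence-weighted Procrustes; the limit is
asserted numerically against the non-rigid path.  Because EM is a local
optimiser, rigid registration multi-starts deterministically from the 24
proper rotations of the cube (centroids aligned) and keeps the start with
the lowest final σ².  This makes the workflow's fixed 90° pre-rotation
about the y-axis (kept as the default pre-step of the multi-layer morph)
harmless for templates in any orientation.

**Multi-layer morphing**: pre-rotation, rigid pass, then repeated
non-rigid passes feeding each output back as the next template until the
maximum per-point Euclidean distance to the current nearest-target
correspondence falls below 0.04 mm (a mean-distance criterion is
available).  Stalling (< 1 % distance reduction between layers) or layer
exhaustion returns a flagged result rather than raising.  The fitted
kernel field extrapolates to arbitrary points, which is how interior
(non-surface) nodes of a solid template are carried by the same smooth
motion.

## IVD construction and proportion control

The hollow IVD morphing target is built from the two adjacent vertebral
endplate patches: their boundary loops (paired by nearest start and
orientation) are connected by 8 rings of wall quads (boundary_count ×
n_layers wall quads exactly).

The hexahedral IVD template shipped here is **synthetic**: a butterfly
(O-grid) cylinder, radius 20 mm, height 10 mm, with 0.7 mm cartilage
endplate (CEP) slabs top and bottom, a nucleus pulposus (NP) core and an
annulus fibrosus (AF) ring.  The NP/AF interface follows a smooth cosine
barrel profile (NP wider towards the endplates); at build time the
interface radius is root-solved so the discrete mid-plane NP area share
is exactly 25 % and the barrel amplitude so the discrete NP volume share
is exactly 40 % — the anatomical proportions the template represents.
(For a prismatic NP both targets cannot hold at once; the barrel is the
geometric reconciliation and is a property of this synthetic template,
not an anatomical claim.)  Hex volumes use a fixed-diagonal 5-tet
decomposition; cross-section areas slice the same tets against the plane,
so the two measures are mutually consistent.  CEP thickness is the
closest opposite-face centroid distance per CEP element projected on the
face normal (exact for slab elements); means outside 0.62 ± 0.29 mm are
flagged.

`morph_ivd` registers the template's outer-surface nodes to the target,
carries interior nodes with the same field, then restores the NP volume
fraction to 0.40 ± 0.005 by radially scaling only the NP/AF interface
nodes about the disc axis (smallest principal axis of the NP node cloud),
solved by bisection.  Correction after (not during) registration is a
design choice; element validity is re-checked and an unreachable target
fraction is reported as a flag, never silently accepted.  Connectivity,
node count and set membership are bitwise invariant under morphing.

Ligaments are line2 elements in seven groups (ISL, SSL, LF, CL, ITL, PLL,
ALL) attached from an editable table of node-ID pairs; attachment
coordinates are curation, not derivation.  Multi-part integration offsets
node/element IDs, prefixes colliding set names, records a part → offset
provenance map and carries tie-constraint metadata (secondary set,
primary set), which round-trips through the INP subset.

## Hexahedral SSM and personalization

Deformation transfer copies each hexahedral node's 3 rows of the
√eigenvalue-scaled mode matrix from its closest point on the mean
triangulated shape (rigid alignment + ICP when the geometries are in
different poses; plain nearest neighbours when alignment is disabled for
co-registered geometry).  Sampling at weights b is coordinate
replacement on the shared template: connectivity, sets and ties never
change, and cohort instances are written as plain `node_id x y z` files
in template *NODE order so regeneration is pure substitution into one
template INP.

Personalization finds b in [−3, 3]^m minimising the sum of squared
normalised errors of measured PI / PT / SS / LL against targets.  Each
parameter error is normalised by that parameter's range over the
seven-level mode-1 sweep, balancing degrees of different magnitude.  The
search is deterministic: a greedy per-mode sweep over the seven SD levels
seeds a bounded trust-region least-squares refinement (the objective is
smooth in b because the geometry is linear in b).  The result is clamped
to never be worse than the mean (b = 0); out-of-reach targets — e.g. a
PI inconsistent with PT + SS — return the best effort with a positive
residual.

## Mesh quality

Hex elements are checked at Gauss points (2×2×2 for trilinear hex8,
3×3×3 for serendipity hex20): an element with any non-positive Jacobian
determinant is an **error** (unusable for FE analysis); the Jacobian
ratio is min/max determinant, with the conventional 0.30–0.80 band
reported as information only.  **Warnings** are valid elements with
Jacobian ratio < 0.30, aspect ratio (longest/shortest edge) > 10, or a
quad corner angle > 160° (reflex corners report their true > 180°
interior angle; bow-tie quads report 180°).  Summary percentages are
taken over the relevant element classes (errors over hexes, angle
warnings over quads) and recompute exactly from the per-element flags.

## Spinopelvic measurement

Measurements are taken in a body-fixed frame: the lateral axis follows
the bicoxofemoral (femoral-head) axis projected to the horizontal, the
vertical stays gravity — as on a properly positioned lateral radiograph —
so all sagittal parameters are invariant to the patient's rotation about
the vertical, and PI (a purely relative angle) is invariant under any
rigid transform.  Constructions: SS = sacral-plate line vs horizontal;
PT = hip-axis→S1-centre line vs vertical; PI = caudal plate normal vs the
S1-centre→hip-axis line (so PI = PT + SS in the sagittal plane); LL =
signed S1-to-L1 superior-endplate angle, lordosis negative, and
LL−PI = PI − |LL| (the convention forced by the exemplar's printed
values); GT at the sacral-plate centre between the continued C7 line and
the hip-axis line; TPA at the hip axis between the T1 and S1 lines;
SVA = anterior offset of C7 from the posterior S1 corner (mm); Cobb =
maximum inter-endplate angle over vertebra pairs on the coronal
projection (automatic end-vertebra choice, manual override possible).

The GAP score sums category points of the PI-proportioned components
(ideal SS = 0.59·PI + 9, ideal LL magnitude = 0.62·PI + 29, ideal
GT = 0.9·PI − 48; LDI = L4–S1 share of L1–S1 lordosis × 100) plus an age
factor (< 60 years adds 1 point): RPV 0/1/3 below −4°/−10°; RLL 0/2/3
below −14°/−25°; LDI 0 in 50–80 %, 1 in 40–50 %, 2 below 40 %, 3 above
80 % (hyperlordotic maldistribution); RSA 0/1/3 above 7°/17°.  Maximum
13.  The whole scheme ships as an editable configuration so any numeric
discrepancy with a given radiographic pipeline is auditable.  Deformity
classes: GAP 0–2 aligned, 3–6 moderate, 7–13 severe; Cobb < 10° none,
10–20° moderate, > 20° severe.  The deformity inclusion filter requires
age 50–75 plus, strictly, |LL − PI| mismatch > 10°, PT > 20° and
SVA > 5 cm.

## Synthetic study conditions

- `make_fixture_family`: low-rank planted-mode families (known mean,
  orthonormal modes, descending variances, isotropic noise, optional
  rigid nuisance within ±30° per axis) for recovery tests.
- `make_spine_constellation` / `make_spine_family`: an idealised
  sagittal-plane spinopelvic landmark constellation realising requested
  PT / SS / LL / kyphosis / Cobb values exactly, with cohort spreads
  typical of an adult-deformity population (PT, SS ≈ ±6°, LL ≈ ±10°,
  kyphosis ≈ ±8° about PT 20° / SS 35° / LL −55° / TK 40°); segmental
  lordosis shares fixed at 30/25/20/15/10 % from L5/S1 up (LDI 55 %).
  Families are generated in a common standing frame; GPA's rotational
  gauge is then the first shape's pose, so frame-dependent parameters
  (PT, SS, SVA) of the aligned mean need not equal the generator means —
  all measurements within one model family remain mutually consistent,
  which is what personalization relies on.
- `make_spine_fe_template`: one hex8 block per vertebral body plus the
  landmark nodes themselves (node IDs 1..P coincide with the
  constellation points) and interspinous line elements.

What passing tests on these conditions show: correctness of the
algorithms (alignment, eigen-recovery, registration convergence, field
transfer, measurement geometry, scoring arithmetic) at desk scale.  What
they do not show: performance on real EOS-derived anatomy — real
surfaces are dense, noisy, with per-vertebra shape detail and
correspondence jitter none of which the constellation has; the cohort
statistics printed by real-data studies (e.g. 95 % compactness at 5
modes, sub-half-millimetre generalization/specificity on 42 patients)
can only be recomputed with the deposited patient meshes.

## Numerical choices

- STL welding tolerance 1e-6 mm, first-occurrence order (preserves
  positional correspondence across corresponding files); binary STL
  writing is bit-stable.
- INP dialect: only *NODE, *ELEMENT (TYPE=, ELSET=), *ELSET, *NSET
  (GENERATE), *TIE are interpreted; all other keyword sections are
  carried verbatim so a template round-trip is bit-faithful outside the
  interpreted subset.  Internal indices 0-based; INP IDs 1-based,
  preserved.
- ICP nearest-neighbour ties resolve to the lowest target index
  (k-d-tree backend, contractually identical to exhaustive search).
- Kernel solves add a 1e-12 jitter; E-steps use log-sum-exp throughout.
- All randomness flows through explicit integer seeds; the pipeline fans
  one global seed out per stage by stable hashing, and re-running a
  config reproduces byte-identical coordinate outputs.

## Limitations

- Mixture covariances are isotropic (σ²I); anisotropic per-component
  covariances are out of scope.
- No posterior sampling of registration parameters; uncertainty is not
  quantified.
- Mesh repair is detection-only (invalid elements are counted and
  flagged; no optimisation-based untangling).
- Units are millimetres and degrees throughout; hex20 volume/section
  measures use the corner nodes (exact for straight-edged elements).
- The GAP category table is a reconstruction of the cited scheme,
  shipped as editable configuration; its ideal-SS and ideal-LL lines are
  verified exactly against the exemplar's printed component values, the
  ideal-GT line to within the exemplar's own rounding (0.08°).
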