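# Methods

## Problem setting

A 4D scanner records a sequence of triangle meshes `V⁽¹⁾ … V⁽ᶠ⁾` of a
moving breast at a fixed frame rate; each frame is reconstructed
independently, so vertex identity carries no meaning across frames.  A
MoCap system simultaneously tracks K ≈ 30 physical markers as corresponded
trajectories `cₖ⁽ⁱ⁾`, possibly in a different coordinate frame, at a
different rate, and with an unknown clock offset.  The package estimates,
for every consecutive frame pair, a continuous map `F⁽ⁱ⁾` sending any
surface point of frame *i* to its material counterpart in frame *i+1*.

All internal lengths are millimetres and all times seconds; errors are
converted to centimetres only at the reporting layer.

## Motion model

The inter-frame motion model is a 3D thin-plate spline

    f(x) = a₀ + aᵀx + Σₖ ωₖ φ(‖x − cₖ⁽ⁱ⁾‖),   φ(r) = r² ln r,  φ(0) = 0,

solved so that each frame-*i* landmark maps exactly onto its frame-(i+1)
partner.  The linear system is the standard augmented form
`[Φ + λI, P; Pᵀ, 0]` with `P = [1, cᵀ]`, solved once with the three
coordinates as a joint right-hand side.  Two conventions are fixed here
because they affect numerics but not the modelling idea:

* the orthogonality **side conditions** `Σωₖ = 0`, `Σωₖcₖᵀ = 0` are
  imposed.  They make the augmented system square and well posed and give
  exact reproduction of affine motion with vanishing kernel weights — the
  convention shared by mainstream scientific-computing TPS implementations
  (scipy's thin-plate RBF uses the same one, and is used as an independent
  cross-check in the tests);
* the kernel logarithm is **natural**; a different base only rescales the
  weights but is fixed for determinism.

Regularization λ defaults to 0 (exact interpolation); a positive λ is
available for near-degenerate landmark configurations and the solver
refuses singular systems with a hint to use it.  Solving needs at least 5
controls, not all collinear.

## Post-alignment and the correspondence field

The TPS transports every vertex of the cropped frame-*i* breast mesh; each
transported vertex is then replaced by its globally nearest point on the
frame-(i+1) surface.  "Nearest point on the surface" is computed exactly:
the query is projected onto every candidate triangle's plane and clamped
to the triangle, so the result always lies on the target mesh.  The
accelerated implementation bounds the search with the nearest-vertex
distance and prunes triangles by centroid distance; the pruning radius
includes the largest centroid-to-corner radius, so the candidate set
provably contains the optimum and the result equals brute force (asserted
against a brute-force oracle over all triangles in the tests).  Ties break
to the lowest face index for determinism.

The paired sets (frame-*i* vertices, aligned vertices) define the dense
correspondence.  A query point x is mapped by solving a local TPS on the
M nearest frame-*i* vertices (ties to lowest index) and their partners and
evaluating it at x.  M = 20 by default: comfortably above the 5-point
solvability minimum, small enough that local solves stay ~10³ flops.  The
value is recorded in every field file.  Degenerate local neighbourhoods
(e.g. locally coplanar samples) escalate to 2M neighbours, then to
λ = 10⁻⁶, then fail loudly.

Registration chains frame pairs sequentially (i → i+1 only); errors
therefore accumulate along the sequence, which the evaluation protocol
makes visible as a frame-wise error curve.

## Calibration

**Spatial.**  A coarse signed axis permutation `R_axis` (user-specified,
e.g. `"y,-x,z"`) roughly orients the MoCap frame; the residual similarity
`(s, R_fine, T)` is then estimated either closed-form from corresponded
pairs (Umeyama's least-squares solution) or, when correspondence is
unknown, by rigid coherent-point-drift with uniform scale — EM over a
Gaussian mixture with fixed defaults (outlier weight 0, tolerance 10⁻⁶,
100 iterations).  Both modes are exposed because frame-1 landmark
labelling may or may not come with a usable ordering.

**Temporal.**  MoCap and scanner clocks differ by an offset δ
(`t_scan = t_mocap + δ`).  Marker spots are visible in the scan texture,
so each frame's high-gray-gradient vertices are extracted as reference
points: per vertex, the maximum of `|g(x) − g(x′)| / (‖x − x′‖ + 10⁻⁵)`
over its min(100, N−1) nearest neighbours, thresholded at mean + 2 SD of
the frame.  A zero-variance gray field selects nothing (uniform texture
carries no alignment signal).  For a candidate δ, the MoCap tracks are
resampled (piecewise-quadratic splines, exact at samples and on quadratic
motion, extrapolation refused) at the shifted scan times and the mean
landmark-to-nearest-reference distance is averaged over frames; frames
whose shifted time leaves the recording are skipped and counted.  δ is
located by a coarse grid over [−10, 10] s in 100 intervals (step 0.2 s)
followed by a fine grid of 100 intervals over ±0.5 s around the coarse
optimum (step 0.01 s).  The fine window is centred on the *coarse*
optimum — the only reading under which the two-stage search is well
defined.

## Breast cropping

Six contour landmarks (ids {0, 1, 10, 17, 25, 26}) bound the breast.  The
crop keeps vertices inside the height slab `[h_min − ψ, h_max + ψ]`
(contour landmark heights, ψ = 30 mm, height axis configurable, default
+z — scanner conventions differ) and anterior to the least-squares breast
plane shifted by ψ against its normal.  The plane passes through the
contour centroid; its normal solves the stacked equations
`(cₖ − c₀)ᵀn = 0` plus one L1-normalization row linearized with the sign
pattern of the SVD total-least-squares normal, then is rescaled to unit
length.  The normal is oriented so that the mean of **all** landmarks —
which sit on the anterior breast surface, the side to keep — has
nonnegative signed distance.  Faces crossing a cut are dropped, never
clipped, and vertex positions are never modified, so cropping is exactly
idempotent.  Disconnected leftovers are removed by face-edge connected
components; every component holding a vertex within 2 mm of a landmark is
retained, falling back to the largest-area component.

## Decimation

Quadric-error-metric edge collapse (area-weighted face-plane quadrics,
optimal collapse position from the 3×3 quadric solve, clamped to the
original bounding box so decimation never inflates the mesh; midpoint and
endpoints as fallback candidates).  Collapses proceed in increasing error
order through a lazily invalidated heap until the vertex target is reached.
Besides baseline-style mesh reduction it provides the even surface
sampling used by the deformation-intensity analysis.

## Downstream analyses and evaluation

* **Virtual landmark tracking** chains the per-pair fields from frame-1
  seed points.
* **Deformation intensity** decimates frame 1 to 100 samples, tracks each,
  and scores trajectory length (mm); full-resolution vertices inherit their
  nearest sample's value (Voronoi colouring — the natural reading of
  per-patch colouring).
* **Control-landmark error** seeds tracking at the frame-1 ground-truth
  landmark positions and reports per-landmark, per-frame Euclidean
  deviation from the ground-truth tracks.
* **Leave-one-out error** excludes each landmark from the motion model in
  turn, rebuilds all fields, and tracks the held-out landmark — the
  non-control accuracy estimate.

Reported SDs pool all (landmark, frame) samples; the pooling convention is
stated in every report header because other populations (per-frame,
per-landmark) are equally defensible.  Frame 1 (error 0 by construction)
is included in the matrices so that frame-wise curves start at the seeding
instant.  A utility builds reduced-rate sub-sequences by keeping one frame
per chunk of n, mirroring how lower-rate evaluation datasets are derived
from a 120 fps recording.

## Synthetic phantom

The phantom is a parametric surface: a gently bowed plate (400 × 400 mm,
60 mm bow) carrying a smooth breast mound (90 mm base radii, 60 mm
protrusion, squared-cosine profile).  A material point is its (u, v)
parameter, so every trajectory is known in closed form.  Defaults mirror
the 10 fps study condition: 11 frames, ~3000 vertices per frame, 30
landmarks (six on the mound base ring as the cropping contour, the rest on
a golden-angle spiral over the mound).

Motion families: `static`; `rigid_translation` (fixed step per frame);
`affine` (fixed small strain pattern per frame); `bounce_swing` — a
vertical damped sinusoid plus a slower lateral sinusoid and a small
non-periodic lateral drift, all scaled by the mound envelope so the apex
moves most and the base ring not at all (2 Hz, (10, 5, 25) mm amplitudes,
0.3 s⁻¹ damping — desk-scale analogues of walking-induced breast motion);
and `tps_from_landmarks`, where each frame is the TPS image of the
previous frame under the landmark motion, making the pipeline's motion
model *exactly correct* — the positive control for exact-recovery tests.
The bouncing deformation is verified non-affine (best-fit affine residual
> 1 mm), so registration tests cannot be passed by a trivial global fit.

With `remesh` on, every frame is sampled on an independently jittered
parameter grid (alternating-parity sizes guarantee consecutive frames
differ in vertex count) — emulating the defining nuisance of real 4D
scans.  With it off, the grid nodes nearest each landmark site are snapped
onto it, making the landmarks exact mesh vertices.  The simulated MoCap
stream resamples the exact tracks at the MoCap rate, shifts timestamps by
−δ*, applies the inverse of a chosen similarity transform, and adds seeded
Gaussian noise (noise enters only the MoCap stream; scan geometry is
exact).  All generation is deterministic under the spec seed.

**What the phantom does not emulate:** scanner reconstruction noise,
holes and topological defects, self-contact, texture imagery beyond
painted Gaussian marker spots, and subject-specific tissue mechanics.
Passing tests therefore demonstrate the correctness and internal
consistency of the algorithms under known smooth motion, not clinical
accuracy on real scans.

## Problem sizes and numerical choices

The test suite and the acceptance script run phantoms of 250–3000 vertices
and 1–11 frames — sizes chosen so the full pipeline, including the 30-fold
leave-one-out rebuild, completes in seconds to a couple of minutes on a
single core while still exercising every code path at the default study
condition.  Interpolation exactness is asserted at 10⁻⁶ mm, affine
reproduction at 10⁻⁸ on the weights, geometry-oracle agreement at 10⁻⁹ mm;
ties in nearest-neighbour and nearest-sample queries always break to the
lowest index, making every pipeline output bit-reproducible under a fixed
seed.

## Known limitations

* Sequential chaining accumulates error over long sequences; no long-range
  or loop-closure alignment is attempted.
* Post-alignment snaps to the nearest surface point, which can slide
  correspondence tangentially where the motion estimate is poor or the
  surfaces are locally parallel-offset.
* The local-TPS field uses frame-*i* vertices as interpolation sites even
  for chained queries that have drifted off the frame-*i* surface; far
  from the surface the map degrades to its affine part.
* The gray-gradient reference extraction assumes marker spots dominate the
  texture gradient; heavily textured surfaces would select spurious
  reference points.
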