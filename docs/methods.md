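# Methods

This note documents the models, numerical choices and study conditions
behind `meshreg`, and what the synthetic experiments do and do not show.

## Surfaces, sampling and metrics

All meshes are closed, manifold triangle surfaces with vertex
coordinates in mm (`validate_mesh` enforces: every edge shared by
exactly two faces, no degenerate faces, ≥ 4 vertices/faces; multiple
closed components are allowed — the seminal vesicles are a pair).

Distances are true point-to-**triangle** distances, not point-to-vertex:
vertex-only distances overestimate and depend on tessellation. The
proximity query is the exact Voronoi-region closest-point-on-triangle
test evaluated per (point, face) pair in a compiled kernel, with a
centroid + circumradius lower-bound rejection; a vectorized numpy path
with KD-tree pruning is the fallback. Tests and the acceptance script
verify it against an independent all-pairs oracle to 1e-9 mm.

Surface sampling is deterministic: every vertex, plus
`ceil(area · density)` interior samples per face placed on a fixed R2
low-discrepancy barycentric pattern. No random seed is involved, so all
metrics are bit-reproducible. Defaults: vertex-only sampling for the
registration objective and correspondences (the standard ICP choice, and
5–10× faster), density 1 sample/mm² plus vertices for reported metrics.

- **Mean bidirectional distance** (the objective): average of the two
  directed mean sample-to-surface distances.
- **Hausdorff distance** (the accuracy metric): larger of the two
  directed maxima over the same sample sets. This is a *sampled*
  Hausdorff distance, an approximation from below of the polyhedral one,
  controlled by the density parameter.

PLY I/O reads ASCII and binary-little-endian files (non-triangular faces
are rejected with a format error) and writes ASCII with `%.17g`
coordinates, so a write/read round trip reproduces `float64` vertex
arrays exactly.

## Registration pipeline

Every step shares one iteration contract. Per iteration:

1. sample bidirectional nearest-surface correspondences at the current
   shape (template samples → target surface, target samples → template
   surface; backward hits are carried by barycentric coordinates);
2. solve the step's linear problem for a *total* update from the step's
   entry shape;
3. accept the update only if the objective does not increase; otherwise
   halve the update in parameter space up to 8 times, and if no damping
   level helps, stop the step at the current stationary point.

Stopping follows the windowed rule: converged when the mean absolute
change of the objective over the most recent `window = 10` iterations is
below `threshold = 0.001` mm ("average … difference" is read as the
mean of absolute consecutive differences — the only reading that is
scale-positive and insensitive to oscillation sign; a mean-displacement
reading would be a config-level alternative); terminated
unconditionally at `max_iterations = 3000`. The same policy applies to
every step and is overridable per step. Damped acceptance makes each
trace non-increasing by construction, and since each step starts from
the previous step's output, end-of-step objectives are non-increasing
along the chain.

**Affine (STEP 1).** Initialization aligns centroids and RMS radii when
that improves the objective (organ meshes from a scanner frame are
nearly pose-aligned, so no rotational pre-alignment is attempted). Each
iteration refits the full 12-parameter affine from entry coordinates to
correspondence targets by least squares. Rank-deficient templates
(coplanar vertices) are rejected.

**Piece-wise affine (STEP 2).** Regions are seeded k-means clusters of
the entry vertices (default 8 regions, seed 0); blending weights are
normalized Gaussians centred on the cluster centres with bandwidth
1.5 × the mean cluster RMS radius, giving a partition of unity and hence
a continuous deformation. Per region, a weighted least-squares affine is
fitted with the blending weights as sample weights. With one region the
code path is identical to the affine step. A region whose total blending
weight falls below 4 effective vertices raises an error suggesting fewer
regions.

**Laplacian step (Algorithm A's STEP 3).** Solves, per iteration,

    min_V ||L V − L V₀||² + λ Σ_c ||v_c − t_c||²

with `L` the cotangent Laplacian (uniform available) of the entry shape
and `L V₀` the entry delta coordinates — refreshed at step entry, not
per iteration, so the globally registered detail is what is preserved
rather than progressively smoothed. Constraints are the bidirectional
correspondences (a deterministic stride subset if
`correspondence_fraction < 1`). The normal equations are solved by
sparse factorization; a residual check guards against silent singular
solves. Default λ = 50: the constraint-dominated regime in which the
method behaves as detail-preserving interpolation, chosen (together with
the FEM gain below) on a pilot cohort at master seed 999, disjoint from
any evaluation seed. λ = 1 leaves a 3 mm bump fitted only to ~1.3 mm
Hausdorff; λ = 50 reaches ~0.16 mm while keeping monotone convergence.

**FEM step (Algorithm B's STEP 3).** The template is a linear-elastic
body at rest in its entry shape. Correspondences attach springs from
surface points to their targets and the iteration solves the total
displacement equilibrium

    (K + B) U = B (targets − V₀),

where `K` is the assembled stiffness and `B` the diagonal spring-weight
matrix (`force_scale · E ·` vertex-area weight at corresponded
vertices). At equilibrium the spring forces are proportional to the
remaining residuals and balance the internal elastic forces. Two
formulations that look closer to a literal force-balance solve were
rejected during development: pure `K u = f` with rigid-mode projection
cannot descend the objective (the spread elastic displacement pushes
already-matched regions off target at any step size), and an
*incremental* spring solve accumulates displacement without memory of
the rest shape, so it interpolates arbitrarily well and erases the
elastic character of the method entirely.

Elements are linear tetrahedra by default, built by Delaunay
tetrahedralization of the vertices, restricted to tetrahedra whose
centroids lie inside the surface (generalized winding number) and
cleaned of zero-volume slivers. Membrane (constant-strain-triangle)
elements are available but are *not* the default: they have no bending
stiffness, which makes the elastic model more permissive to local
surface deformation than the Laplacian — the opposite of how volumetric
elastic registration behaves. Defaults E = 1 kPa, ν = 0.3,
`force_scale = 5` (only the ratio of gain to E matters); the gain places
the FEM in a visibly stiffer regime than the Laplacian step, consistent
with its elastic-body modelling assumption. Material constants are not
claimed to match any particular clinical implementation; all are
config-exposed.

**Correspondence pruning.** Classical robust-ICP pruning (drop pairs
beyond 3 × the median residual) is implemented but **off by default**:
on clean closed surfaces the median residual collapses toward zero once
most of the surface matches, so the rule discards exactly the
informative correspondences (e.g. the unmatched bump) and stalls both
local steps. When enabled, a 90th-percentile floor caps pruning at the
worst decile. Real contour data with outliers would motivate turning it
on.

**Algorithms.** A = affine → piece-wise affine → Laplacian;
B = affine → piece-wise affine → FEM; C = global only. Registration is
organ-wise and fully independent per target; no inter-organ collision
handling. Template inputs are never mutated, and identical inputs and
configs give bitwise-identical results (the only stochastic ingredient,
k-means, is seeded).

## Template model and statistical shape model

The template for an organ is built by shape matching: the first
subject's mesh is registered onto every construction subject (Algorithm
A by default), which yields corresponded meshes sharing its topology by
construction, and the average template is the coordinate-wise mean.
Construction is single-pass by default; re-registration from the updated
average is exposed as `iterations`. No Procrustes pre-alignment is
performed beyond the pipeline's own affine step. Averaging is only
meaningful for registrations that succeed; a shape and its point
reflection average toward the centroid (documented hazard, tested).

The shape model is PCA of the stacked corresponded coordinates:
orthonormal displacement modes with population-convention standard
deviations (divisor k, so two training shapes project to weights exactly
±1), canonical sign (largest-magnitude component positive), zero-variance
modes dropped. `sample(w) = mean + Σ wⱼ sⱼ modeⱼ`; projection inverts it
on the mode span, and reconstruction with all modes reproduces training
shapes to round-off.

## Synthetic cohorts: what they emulate

The generator stands in for clinical contour data. Study conditions:

- **Volumes** (cm³) are truncated normals per organ — prostate
  26.8 ± 10.6 (9.0–90.5), seminal vesicles 7.0 ± 3.5 (1.3–19.8), rectum
  59.9 ± 25.2 (23.6–203.6), bladder 150.0 ± 79.9 (55.1–442.6) — with the
  location parameter calibrated so the *truncated* mean equals the
  published mean (the naive parameterization is biased by ~+18 cm³ for
  the asymmetrically clipped bladder). Meshes are rescaled after
  deformation, so every mesh's enclosed volume equals its drawn volume
  exactly.
- **Base shapes**: ellipsoids for prostate (axis ratios 1.0/0.95/0.85)
  and bladder (1.0/1.0/1.15); a bent capsule for the rectum; a pair of
  strongly bent capsules for the seminal vesicles.
- **Large-scale variation**: per-subject tube bend angle (rectum
  60° ± 28°, SVs 100° ± 30°), a secondary orthogonal S-bend for the
  rectum (± 25°), tube aspect jitter, SV splay (± 18°), and log-normal
  axis-ratio jitter for the ellipsoidal organs — bending, filling and
  pose effects that global transforms cannot fully fit.
- **Smooth fields**: random plane-wave superpositions along vertex
  normals, correlation length ~1.5 × the organ's sphere-equivalent
  radius (22–49 mm), amplitude means 2–6 mm clipped per organ (bladder
  largest, SVs smallest), plus a detail component at 0.35 × the length
  and 0.15 × the amplitude.
- **Safety**: face-flip and folded-sheet (winding-number) checks reject
  self-intersecting draws; inside a cohort such rare draws are retried
  deterministically with attenuated amplitude and shape variation.
- **Splits**: a template-construction set and a disjoint evaluation set
  (defaults 5 and 20 subjects), mirroring the first-k / remaining
  patients design of template-based studies. All randomness derives from
  one master seed.

Deformation magnitudes were calibrated once, on a pilot cohort at master
seed 999, so that global-only registration degrades to the several-mm
Hausdorff regime reported for clinical global registration while
Algorithm A stays sub-millimetre on the compact organs; they were then
frozen. The experiment seeds used by the tests and the acceptance script
are disjoint from the pilot seed.

**What passing tests show — and don't.** The synthetic cohort
demonstrates the *mechanism*: the accuracy ordering A ≤ B < C per organ,
the Laplacian advantage on high-curvature organs, monotone convergence,
and exact template/SSM recovery. It does not demonstrate clinical
accuracy: real contours have observer variability, sharper creases,
non-radial topology-free deformation, neighbouring-organ contact, and
resolution far above the default tessellation (icosphere subdivision 2,
~160–400 vertices per organ, chosen so the full 260-registration
comparison runs in minutes on one CPU). Absolute Hausdorff values from
the synthetic study are therefore not comparable to clinical tables,
only their ordering and structure.

## Numerical choices and degenerate inputs

- Least-squares solves use `numpy.linalg.lstsq` (dense, per region) and
  sparse LU (`scipy.sparse.linalg.factorized`) with explicit residual
  checks where a singular system could otherwise pass silently.
- Damping blends in parameter space (affine parameters, vertex
  positions, displacement fields) with factors 1, ½, …, 1/256.
- Ties and stalls: if no damping level improves the objective the step
  reports `converged` at the current iterate — a stationary point of the
  alternation. The stall point is floating-point-path dependent;
  rigid-motion equivariance of a full step holds to ~1e-5 mm even though
  the metrics themselves are invariant to ~1e-12.
- Degenerate inputs raise early with context: open or non-manifold
  meshes, rank-deficient templates, isolated vertices, zero-area
  elements, inverted tetrahedra, regions with < 4 effective support
  vertices, empty constraint sets.
- `check_convergence` gives the iteration cap precedence over the window
  statistic (a trace that reaches the cap was by definition never
  stopped by the window earlier).

## Known limitations

- Registration quality is bounded by tessellation; the sampled Hausdorff
  distance under-reports the polyhedral one between samples.
- Piece-wise affine fitting estimates each region's transform from
  weighted correspondences rather than minimizing the blended residual
  jointly; with strongly overlapping weights the alternation can stall
  above the true optimum (Algorithm C's accuracy reflects this).
- Linear (small-strain) elasticity is assembled once on the entry shape;
  large deformations are outside its validity, which is acceptable here
  because STEP 3 only refines an already-aligned shape.
- Delaunay tetrahedralization of surface vertices can under-resolve thin
  concave interiors; uncovered vertices lose elastic coupling (springs
  still constrain them).
- No inter-organ collision handling; organs are registered
  independently.
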