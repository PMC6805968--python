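# meshreg

Global-to-local registration of pelvic-organ surface meshes.

In radiotherapy of the prostate region, the prostate, seminal vesicles,
rectum and bladder are delineated as closed triangle surfaces, and the
same organ looks different in every patient (and on every day): volumes
change, tubes bend, the bladder fills. Deforming one *template* mesh onto
each patient's *target* mesh gives every subject the same vertex/face
topology — dense point-to-point correspondence — which is what
population statistics, statistical shape models and contour-based dose
accumulation are built on.

`meshreg` implements a sequential **global-to-local** registration of a
template mesh T onto a target mesh X:

1. **STEP 1 — affine.** ICP-style alternation: nearest-surface
   correspondences in both directions, then a linear least-squares fit of
   the 12-parameter affine map.
2. **STEP 2 — piece-wise affine.** Template vertices are clustered into
   regions (seeded k-means); each region carries its own affine
   transform, blended by a Gaussian partition of unity so the deformation
   stays continuous.
3. **STEP 3 — local deformation**, either
   - **Laplacian-based** (Algorithm **A**): solve
     `min ||L V − L V₀||² + λ Σc ||v_c − t_c||²`, where `L` is the
     discrete (cotangent) Laplacian, `L V₀` the delta coordinates of the
     globally registered shape (preserving surface detail), and the
     positional constraints `c` are nearest-surface correspondences; or
   - **FEM-based** (Algorithm **B**): treat the template as a
     linear-elastic body (linear tetrahedra on a Delaunay interior mesh)
     and solve the equilibrium `(K + B) U = B (targets − V₀)` in which
     correspondence springs `B` pull the surface onto the target against
     the internal elastic forces `K U`.

   Algorithm **C** stops after STEP 2 (global registration only).

Every step minimizes the **mean bidirectional distance** (the average of
the two directed mean point-to-surface distances, in mm) and stops when
the mean absolute change of that objective over the most recent 10
iterations falls below 0.001 mm, or at 3000 iterations. Accuracy is
reported as the (sampled) **Hausdorff distance** between the deformed
template and the target surface.

Around the registration core the package provides:

- `mesh_core` — `TriMesh` container, ASCII/binary PLY I/O, exact
  point-to-triangle proximity queries, deterministic surface sampling,
  and the distance metrics;
- `template` — average-template construction by shape matching
  (register patient 1's organ onto each subject, average the
  corresponded coordinates) and a PCA statistical shape model
  (`mean + Σ wⱼ·sⱼ·modeⱼ`);
- `synthetic` — a deterministic generator of four-organ cohorts whose
  volume distributions match published 200-patient statistics and whose
  shapes vary by large-scale smooth deformation (bending, splay, axis
  ratios) plus small-scale detail;
- `evaluation` — median/IQR tables, cumulative Hausdorff histograms,
  threshold proportions, and a one-call cohort comparison experiment;
- a `meshreg` command-line interface (`synth`, `register`, `cohort`,
  `template`, `ssm`, `summarize`).

## Worked example

```python
from meshreg.synthetic import OrganSpec, generate_organ, perturb_mesh
from meshreg.pipeline import algorithm_a, algorithm_c, run_registration

template = generate_organ(OrganSpec("prostate", deformation=(22.0, 0.0)))
target = perturb_mesh(template, smoothness=22.0, amplitude=3.0, seed=42)

for spec in (algorithm_a(), algorithm_c()):
    res = run_registration(template, target, spec)
    m = res.final_metrics
    print(f"Algorithm {res.algorithm}: Hausdorff {m.hausdorff:.3f} mm, "
          f"mean bidirectional {m.mean_bidirectional:.3f} mm, "
          f"iterations per step {[t.iterations_run for t in res.per_step]}")
```

prints

```
Algorithm A: Hausdorff 0.320 mm, mean bidirectional 0.029 mm, iterations per step [5, 5, 14]
Algorithm C: Hausdorff 3.093 mm, mean bidirectional 0.693 mm, iterations per step [5, 5]
```

The target here is the template displaced by a smooth random
surface-normal field of 3 mm amplitude. Global registration alone
(Algorithm C) cannot represent that deformation and leaves a ~3 mm
Hausdorff error; adding the Laplacian local step (Algorithm A) brings the
deformed template to within a third of a millimetre of the target
surface, at sub-0.1 mm mean surface distance.

The same flow from the shell:

```bash
meshreg synth --n-subjects 3 --n-template 2 --seed 0 --out cohort/
meshreg register --template cohort/tpl001_prostate.ply \
                 --target cohort/eval001_prostate.ply \
                 --algorithm A --out result/
meshreg cohort --template cohort/tpl001_prostate.ply \
               --manifest cohort/manifest.csv --algorithm A --out metrics.csv
meshreg summarize --metrics metrics.csv \
                  --out-summary summary.csv --out-histograms hist.csv
```

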