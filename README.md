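# vesseltrace

Graph-based tracing of retinal vessel trees from binary segmentations.

Structural analysis of the retinal vasculature (diabetic retinopathy,
glaucoma, hypertensive retinopathy) needs each vessel tree traced
separately from a fundus image. Segmentation alone gives a binary
vessel map; the hard part is the *crossover* — where two trees cross,
the skeleton fuses into one junction and local tracking cannot tell
which branch continues which vessel. `vesseltrace` resolves the
network globally:

1. the mask is thinned to a skeleton with per-pixel radii, and cut
   into **segments** (chains between terminal/branching points);
   terminals inside the optic disk are **roots**, one per tree;
2. segments become nodes of an undirected graph; a junction with m
   incident segments forms an m-clique (3 = branching/termination,
   4 = crossover, 5/6 = crossover at a branching);
3. every segment gets a **modified Shreve order** μ: leaves get 1 and
   orders add up clique-wise toward the roots (for a tree, the root's
   μ equals its leaf count), with an angle-based rule to break
   deadlocks at terminations;
4. each clique keeps only edges between its highest-order members and
   the rest (**graph simplification**), removing sibling edges that
   leak labels between touching branches;
5. an **affinity matrix** W scores each remaining pair of segments by
   the angle θ their ends make at the junction, using
   f1(θ) (piecewise, plateau −sin^k θ_c, then k·cos θ),
   f2(θ) = k·cos θ and f3(θ) = k + k·sin θ, with clique-specific
   rules that reward through-going continuations (θ→180°) and damp
   implausible ones (defaults k = 5, θ_c = 80°);
6. with S = D^(−1/2) W D^(−1/2), root labels propagate by
   **transductive inference**: Y(t+1) = α S Y(t) + (1−α) Y(0)
   (α = 0.9, stop at Frobenius change ≤ 1e−5), converging to
   (1−α)(I−αS)^(−1) Y(0); each segment takes its argmax tree, and
   every traced tree is exported as an acyclic SWC morphology.

A seeded synthetic-scene generator builds ground-truthed vascular
scenes (trees of controlled Shreve complexity around a central disk,
spread angle γ between adjacent trees) so the full stack is testable
without any external data. A fusion module merges complementary
binary segmentations by vessel calibre and bridges broken branches
with cubic extrapolation. See `docs/methods.md` for the model details
and design choices.

## Worked example

```python
import numpy as np
from vesseltrace import (SceneSpec, TreeSpec, Complexity,
                         compose_scene, run_trace_pipeline, evaluate_labeling)

spec = SceneSpec(n_trees=4, spread_angle_gamma=30.0,
                 tree_specs=[TreeSpec(complexity=Complexity.MEDIUM)] * 4)
scene = compose_scene(spec, np.random.default_rng(0))

result = run_trace_pipeline(scene.mask, disk=scene.disk)
print("stage counts:", result.stage_counts)

metrics = evaluate_labeling(result, scene)
print(f"segment accuracy: {metrics['segment_accuracy']:.3f} "
      f"over {metrics['n_segments']} segments")
print(f"crossover cliques: {metrics['n_crossover_cliques']}, "
      f"resolved correctly: {metrics['crossover_accuracy']:.2f}")
```

prints

```
stage counts: {'segments': 79, 'junctions': 36, 'roots': 4,
 'cliques_by_size': {3: 25, 4: 10, 5: 1}, 'edges_full': 144,
 'edges_simplified': 93}
segment accuracy: 0.873 over 79 segments
crossover cliques: 11, resolved correctly: 0.36
```

Four medium-complexity trees packed at γ = 30° produce 79 segments
meeting at 36 junctions, including 11 crossover cliques (sizes 4–5).
Simplification prunes the 144 clique edges to 93. 87% of segments are
assigned to the correct tree (labels matched to ground truth by a
Hungarian assignment); the stricter clique-grouping score counts a
crossover as resolved only when *all* of its member segments are
labeled exactly right. Isolated trees are traced perfectly — errors
concentrate where branches of different trees tangle.

The same pipeline is available from the shell:

```bash
vesseltrace synth --dataset 2 --n-per-subset 5 --seed 0 --out scenes/
vesseltrace trace --mask scenes/d2_n7_000_mask.png \
    --disk scenes/d2_n7_000_disk.png --out traced/
vesseltrace eval --pred traced/labels.tsv \
    --truth scenes/d2_n7_000_truth.png --segments traced/segments.tsv
```

`trace` writes segment/ordering/weight tables (TSV, Matrix Market), a
colored overlay PNG and one SWC file per traced tree; `fuse` merges
three binary segmentations into a connected skeleton with radii.

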