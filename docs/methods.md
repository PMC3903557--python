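# Methods

`vesseltrace` separates a retinal vessel network, given as a binary
segmentation, into the disjoint rooted trees that compose it. The
difficulty is the *crossover*: where two vessel trees cross, the
skeleton forms a single junction blob and purely local tracking cannot
tell which branch continues which. The package follows a graph-based
formulation: make vessel *segments* the nodes of an undirected graph,
encode how plausibly two segments continue one another in an affinity
matrix built from junction geometry, and then let the known root
segments (those entering the optic disk) propagate their tree labels
over the graph by transductive inference.

## Pipeline

1. **Skeletonization.** The mask is thinned to a one-pixel skeleton;
   every skeleton pixel keeps the Euclidean distance to the nearest
   background pixel as its vessel radius. Pixels are classified by
   their 8-neighbour count on the skeleton: 1 → terminal, 2 → body,
   ≥ 3 → branching. The default thinning is Zhang–Suen
   (`skimage.morphology.skeletonize`); the medial-axis transform is
   available as an option but grows "fishbone" branches toward the
   corners of wide strokes, which pollute segment extraction with
   spurious tips. Terminals inside the optic-disk region are *roots*;
   the number of roots equals the number of trees to trace.

2. **Segments and junctions.** Maximal chains of body pixels bounded
   by terminal/branching pixels become segments. Mutually adjacent
   branching pixels (thick junction blobs) are merged into a single
   junction at their centroid. A junction with m incident segments
   yields an m-clique in the dual graph: 3 = branching or termination,
   4 = simple crossover, 5/6 = crossover coinciding with a branching.

3. **Spur removal.** Skeletonizing a crossover often splits one 4-way
   junction into two 3-way junctions joined by a short spurious
   connector. A connector between two 3-way junctions is deleted — and
   the junctions merged back into one 4-way junction — when its length
   is at most `C_critical` (default 10 px) and its mean flanking line
   angle β is at most `beta_critical` (default 70°). β is measured per
   junction as the smallest undirected line angle between the
   connector and a continuing branch, averaged over the two junctions;
   the procedure iterates to a fixed point, so it is idempotent. The
   restriction to 3-way junction pairs is deliberate: without it the
   rule cascades in dense crossover regions and merges many junctions
   into blobs with more incident segments than the clique taxonomy
   supports.

4. **Modified Shreve ordering.** Classic Shreve stream ordering gives
   every leaf order 1 and each confluence the sum of its upstream
   orders, so a tree root's order equals its leaf count (the tree's
   magnitude). The vessel variant works clique-wise: a 3-clique with
   two ordered members gives the third their sum; a 4-clique with two
   ordered members gives *both* remaining members the sum; 5- and
   6-cliques fire with three and four ordered members. When nothing
   can fire, the deadlock is broken at the 3-clique with exactly one
   ordered member whose two unordered segments meet at the smallest
   angle (these junctions are terminations or skeleton artefacts);
   both receive order μ+1 and the clique is remembered as
   deadlock-fired. Two further fallbacks exist purely for robustness
   on rendered scenes and are tagged in the provenance map: RESIDUAL
   (a junction whose ordered members are unusable by the arity rules,
   e.g. root segments, assigns max+1) and SEED (a component with no
   leaves at all — two vessels terminating on each other — seeds its
   root segments at order 1). Ties in the deadlock rule break on the
   junction's (row, col).

5. **Graph simplification.** Within each clique the members attaining
   the maximal order (V_CH) are topologically senior; only the
   complete bipartite edge set V_CH × V_CNH survives. This removes
   sibling edges through which labels could leak between branches
   that merely touch. Cliques whose members all share one order (only
   possible in cycles) keep their edges, with a warning.

6. **Affinities.** Each segment end carries a unit direction pointing
   out of the segment into its junction. Without an intensity image
   the direction is the endpoint tangent of a quadratic arc-length fit
   over the last `orientation_window` (default 10) chain points — an
   averaged secant systematically lags on curved vessels (≈8° on a
   30 px-radius arc) while the endpoint fit stays within a few
   degrees. With an image, directions come from the eigenvector of
   the Gaussian-smoothed Hessian with the smaller-magnitude eigenvalue
   (the along-ridge direction), sign-aligned and averaged over the
   same window. The junction angle θ between two ends, folded into
   [0°, 180°), is ≈180° for a straight continuation. Three profiles
   convert angles into weights (k = 5, θ_c = 80° by default):

   * f1(θ): −sin^k θ below θ_c, the constant −sin^k θ_c up to
     θ\* = arccos(−sin^k θ_c / k), then k·cos θ. θ\* is the unique
     value making f1 continuous; for k < ≈1 the plateau never meets
     k·cos θ and θ\* is capped at 180°. exp(−f1) is non-decreasing in
     θ: straighter continuations never get smaller affinity.
   * f2(θ) = k·cos θ and f3(θ) = k + k·sin θ: at any obtuse angle,
     exp(−f2) ≥ 1 ≥ exp(−f3), so a favourable crossover pair always
     dominates an unfavourable one.

   Per clique:

   * **3-clique, ordinary branching (case A):** every surviving edge
     gets exp(−f1(θ)). A clique is "ordinary" when the ordering never
     needed the deadlock rule there.
   * **3-clique, termination / split crossover (case B / C):** the two
     deadlock-ordered members are the vessel continuing through the
     junction; their edge gets exp(−f1(θ)) *even when simplification
     removed it* (both lie in V_CH, yet they belong to one tree and
     the affinity must say so). The worse-aligned of the two remaining
     pairs is damped by the sign-flipped exp(+f1(ψ)); the last pair
     keeps the case-A weight when it survives. Cases B and C are told
     apart by whether some junction-to-junction member is shorter than
     `C_critical`; both are weighted identically.
   * **4-clique:** the entry pixels of the four members around the
     junction admit exactly one chord pairing whose two chords cross
     inside their convex hull; those two pairs are the through-going
     vessels and get exp(−f2(θ)) (again written into W even if
     simplification dropped the edge); other surviving edges get
     exp(−f3(θ)). Degenerate (collinear) geometry falls back to
     pairing each member with its largest-angle partner, with a
     warning.
   * **5/6-clique:** the two highest-order members seed two groups
     (they lie on opposite sides of the crossover); every other member
     joins the seed it meets at the larger angle. Within-group
     surviving edges get exp(−f1(θ)), cross-group ones exp(+f1(θ)).
     Junctions with more than six incident segments abort with an
     error in strict mode; the pipeline runs them through the same
     two-seed rule with a warning, accepting degraded accuracy there.

   W is symmetric with a zero diagonal; its sparsity pattern is the
   simplified edge set plus the restored through-pair edges described
   above.

7. **Label propagation.** With S = D^(−1/2) W D^(−1/2), iterate
   Y(t+1) = α·S·Y(t) + (1−α)·Y(0) from the one-hot root seed matrix
   until the Frobenius norm of the change is ≤ ε (α = 0.9, ε = 1e−5,
   max 10 000 iterations). For α < 1 the spectral radius of αS is
   below one, so the iteration converges to
   (1−α)(I−αS)^(−1)Y(0) — implemented separately as a closed-form
   solver and used as the oracle in tests. Root rows are not clamped
   during iteration; each segment then takes the argmax column, with
   ties resolved toward the label of its strongest neighbour and root
   rows forced to their own tree. Segments in rootless components
   stay unassigned.

8. **Self-intersection resolution.** A traced tree may still contain
   cycles (its own branches crossing). For export as a rooted tree
   (SWC; DIADEM-style scoring) a maximum spanning tree under
   junction-angle edge weights is extracted from the simplified
   labeled subgraph and rooted at the root segment: on a cycle-free
   tree this is the identity, and at every conflicted junction a
   segment stays attached to the chain it continues most smoothly —
   the same principle the affinities use.

## Synthetic scenes

The generator provides ground-truthed benchmarks. A scene is a central
optic disk with `n_trees` trees radiating from it, adjacent tree axes
separated by the spread angle γ (counter-clockwise); if n·γ exceeds
360° the separation wraps to 360°/n. Each tree grows by recursive
binary branching: a trunk along the axis, children deviating by angles
drawn from 18–38° to either side, branch lengths 26–42 px decaying by
0.85 per generation (minimum 12 px), and per-step heading jitter of
2° with mean reversion — values chosen to mimic the look of retinal
vessel trees at fundus-image scale (512² canvas, disk radius 40,
stroke width 3). Complexity classes are defined by the Shreve order of
the root segment, i.e. the leaf count: LOW 2–5, MEDIUM 5–10, HIGH
11–16 (the class is stated as ">10"; an upper bound is required for
generation and canvas fit). Trunks enter the disk at two alternating
depths so root tips stay distinct even at small separations. Trees
whose extent would leave the canvas are rescaled with a warning.

Three benchmark datasets mirror the controlled studies: dataset 1
varies the complexity mix over five subsets (8 trees, γ = 30°);
dataset 2 varies the tree count over {3, 5, 7, 9, 11, 12} (mixed
complexity, γ = 30°); dataset 3 varies the angular coverage over
{360°, …, 60°} for 8 mixed trees — here the stated angle is read as
the *total* coverage (separation γ/8), the only interpretation under
which all six subsets are geometrically realizable and crossover
density grows as the angle shrinks.

Per-pixel truth is kept per tree (crossing pixels retain all
identities). Evaluation maps each traced segment to its
majority-overlap truth tree, matches predicted and true labels by a
Hungarian assignment on the overlap matrix (tree numberings are not
canonical), and reports segment-label accuracy, per-tree
precision/recall, and the fraction of 4/5/6-cliques whose member
grouping matches the truth grouping. This metric is a proxy for
tree-reconstruction quality, not the DIADEM score; SWC export enables
external DIADEM scoring.

What the generator does *not* emulate: intensity/texture (scenes are
binary, so Hessian orientations are exercised only via the optional
image path), vessel width variation along a branch, central reflex,
pathology, or the capillary bed. Passing tests on these scenes show
the graph machinery resolves geometrically well-posed crossings; they
do not certify performance on fundus photographs, where segmentation
quality dominates.

## Segmentation fusion

For real images the tracer consumes a binary mask produced upstream.
The fusion module implements the calibre-guided merge of three masks
with complementary failure modes (highest-F1 supervised output,
highest-recall supervised output, unsupervised wavelet-style output):
per-segment median diameters (2× the distance-transform radius) are
computed on the primary skeleton; segments thinner than the mean
segment diameter d_m are replaced by the corresponding high-recall
segments, segments thicker than d_m + 1 SD by the corresponding
unsupervised ones. Correspondence is maximal skeleton overlap within
a 2 px dilation band — the best-overlapping donor is taken whole, and
further donors join when at least half their length lies in the band
(so one merged thick vessel can be replaced by two parallel thin
ones); replacement endpoints snap to the retained skeleton within
3 px. Remaining disconnected components are bridged by fitting a
cubic in the component's principal-axis frame and extending it one
pixel at a time (budget 30 px) until it touches another component;
bridged pixels take an inverse-distance-weighted convex combination
of the two sides' radii, so bridged radii never leave the donor
range, and the component count never increases.

## Numerical choices and degenerate inputs

* Angles are capped at 179.999° so exactly antiparallel directions
  stay inside f1's half-open domain.
* One-pixel segments take their orientation from the junction
  geometry (vector from pixel to junction centroid).
* Junction clusters are merged by 8-connectivity; a 2-pixel loop
  segment at a junction (skeleton noise) is ordered by the RESIDUAL
  rule rather than crashing the frontier.
* Edges shared by two junctions (a two-segment cycle) keep the larger
  of their two weight assignments.
* All stages are deterministic: segments are numbered by scan order
  of their first pixel, junctions by scan order of their first
  branching pixel, cliques sorted by junction point, and the
  generator is driven entirely by a seeded `numpy` Generator.

## Known limitations

* Junctions with more than six incident segments are outside the
  clique taxonomy; the pipeline handles them by the generalized
  two-seed rule but accuracy there is poor, and tightly tangled
  regions (nearly parallel crossings at small spread angles) remain
  the dominant error source on crowded scenes.
* The exp(+f1) damping of Eqs for termination cliques yields weights
  in (0, 1] rather than a true penalty; a stronger penalty would
  require departing from the published form.
* Segment-label accuracy on crowded synthetic scenes is nearly
  insensitive to the contrast parameter k and to graph
  simplification: the angular rules already decide cleanly at
  well-posed junctions, and at ill-posed ones no weighting helps.
  Both mechanisms matter more for tree-topology metrics on real
  images than for segment counts on these scenes.
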