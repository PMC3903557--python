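"""End-to-end tracing pipeline and its evaluation metrics.

Stages: skeletonize → spur removal → dual graph → modified Shreve
ordering → graph simplification → orientation affinities → label
propagation → per-tree self-intersection resolution.  The result keeps
every intermediate product for inspection and export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import SegmentSet, SkeletonMap
from .graph import VesselGraph, build_graph
from .ordering import OrderingMap, order_segments
from .orientation import WeightParams, segment_orientations
from .propagate import (
    PropagationParams,
    TreeLabeling,
    UNASSIGNED,
    assign_tree_labels,
    make_seed_matrix,
    normalize_affinity,
    propagate_labels,
    resolve_self_intersections,
)
from .simplify import simplify_graph
from .skeletonize import extract_segments, remove_spurious_segments, skeletonize_mask
from .synthetic import SyntheticScene
from .weights import WeightMatrix, assemble_weight_matrix

__all__ = ["TraceConfig", "TraceResult", "run_trace_pipeline", "evaluate_labeling"]

log = logging.getLogger(__name__)


@dataclass
class TraceConfig:
    """Pipeline settings; the defaults are the method's working point
    (k=5, θc=80°, C_critical=10, β_critical=70°, α=0.9, ε=1e-5)."""

    weights: WeightParams = field(default_factory=WeightParams)
    propagation: PropagationParams = field(default_factory=PropagationParams)
    simplify: bool = True
    remove_spurs: bool = True
    skeleton_method: str = "thin"


@dataclass
class TraceResult:
    skeleton: SkeletonMap
    segments: SegmentSet
    graph: VesselGraph                  # full dual graph (pre-simplification)
    simplified: VesselGraph             # graph used for the affinity matrix
    ordering: OrderingMap
    weight_matrix: WeightMatrix
    scores: np.ndarray                  # propagated label matrix Y(T)
    labeling: TreeLabeling
    trees: dict[int, nx.DiGraph]        # root id → acyclic parent-child tree
    orientations: dict
    stage_counts: dict[str, object]


def run_trace_pipeline(
    mask: np.ndarray,
    image: np.ndarray | None = None,
    disk: np.ndarray | None = None,
    config: TraceConfig | None = None,
) -> TraceResult:
    """Trace a binary vessel mask into disjoint rooted trees.

    ``disk`` (boolean raster) marks the removed optic-disk region whose
    interior terminals become roots; ``image`` optionally supplies
    intensity for Hessian-based orientations.
    """
    config = config or TraceConfig()
    wp = config.weights

    skel = skeletonize_mask(mask, method=config.skeleton_method)
    segset = extract_segments(skel, disk=disk)
    if config.remove_spurs:
        segset = remove_spurious_segments(
            segset, beta_critical=wp.beta_critical, c_critical=wp.c_critical,
            image=image, params=wp,
        )
    orientations = segment_orientations(segset, image=image, params=wp)
    vg = build_graph(segset, strict=False)
    om = order_segments(vg, orientations)
    simplified = simplify_graph(vg, om) if config.simplify else vg
    wm = assemble_weight_matrix(simplified, om, orientations, wp)

    Y0, roots = make_seed_matrix(wm.ids, vg.root_ids)
    S = normalize_affinity(wm.W)
    Y = propagate_labels(S, Y0, config.propagation)
    labeling = assign_tree_labels(Y, wm, vg.root_ids)

    trees: dict[int, nx.DiGraph] = {}
    for root, members in labeling.trees().items():
        if root == UNASSIGNED:
            continue
        trees[root] = resolve_self_intersections(
            members, simplified, orientations, root_id=root
        )

    clique_sizes: dict[int, int] = {}
    for c in vg.cliques:
        if c.size >= 3:
            clique_sizes[c.size] = clique_sizes.get(c.size, 0) + 1
    counts = {
        "segments": len(segset),
        "junctions": len(segset.junctions),
        "roots": len(vg.root_ids),
        "cliques_by_size": clique_sizes,
        "edges_full": vg.graph.number_of_edges(),
        "edges_simplified": simplified.graph.number_of_edges(),
    }
    log.info("trace: %s", counts)
    return TraceResult(
        skeleton=skel, segments=segset, graph=vg, simplified=simplified,
        ordering=om, weight_matrix=wm, scores=Y, labeling=labeling,
        trees=trees, orientations=orientations, stage_counts=counts,
    )


def _truth_per_segment(result: TraceResult, scene: SyntheticScene) -> dict[int, int]:
    """Majority-overlap ground-truth tree (1-based) per predicted segment."""
    truth: dict[int, int] = {}
    for seg in result.segments:
        votes = np.array([
            sum(1 for p in seg.pixels if tm[p]) for tm in scene.tree_masks
        ])
        truth[seg.id] = int(np.argmax(votes)) + 1 if votes.max() > 0 else 0
    return truth


def evaluate_labeling(result: TraceResult, scene: SyntheticScene) -> dict:
    """Score a tracing against the generator's ground truth.

    Predicted tree ids (root segment ids) carry no canonical relation
    to the generator's tree numbers, so predicted and true labels are
    matched by a Hungarian assignment on the segment-overlap matrix;
    accuracy is the fraction of segments whose matched label agrees
    with their majority-overlap truth.  Also reports per-tree precision
    and recall and the fraction of 4/5/6-cliques whose member grouping
    matches the truth grouping (crossover-resolution accuracy).
    """
    truth = _truth_per_segment(result, scene)
    pred = result.labeling.label
    seg_ids = sorted(pred)
    if not seg_ids:
        raise ValueError("empty prediction")

    pred_labels = sorted({v for v in pred.values() if v != UNASSIGNED})
    true_labels = sorted({v for v in truth.values() if v != 0})
    overlap = np.zeros((len(pred_labels), len(true_labels)))
    pidx = {v: i for i, v in enumerate(pred_labels)}
    tidx = {v: i for i, v in enumerate(true_labels)}
    for sid in seg_ids:
        if pred[sid] != UNASSIGNED and truth[sid] != 0:
            overlap[pidx[pred[sid]], tidx[truth[sid]]] += 1
    ri, ci = linear_sum_assignment(-overlap)
    mapping = {pred_labels[i]: true_labels[j] for i, j in zip(ri, ci)}

    correct = sum(
        1 for sid in seg_ids
        if pred[sid] != UNASSIGNED and mapping.get(pred[sid]) == truth[sid]
    )
    accuracy = correct / len(seg_ids)

    per_tree = {}
    for t in true_labels:
        tp = sum(1 for sid in seg_ids
                 if truth[sid] == t and mapping.get(pred[sid]) == t)
        fp = sum(1 for sid in seg_ids
                 if truth[sid] != t and mapping.get(pred[sid]) == t)
        fn = sum(1 for sid in seg_ids
                 if truth[sid] == t and mapping.get(pred[sid]) != t)
        per_tree[t] = {
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "recall": tp / (tp + fn) if tp + fn else 0.0,
        }

    cross_total = cross_correct = 0
    for clique in result.graph.cliques:
        if clique.size < 4:
            continue
        cross_total += 1
        pred_groups = {}
        true_groups = {}
        for m in clique.members:
            pred_groups.setdefault(pred[m], set()).add(m)
            true_groups.setdefault(truth[m], set()).add(m)
        if set(map(frozenset, pred_groups.values())) == set(
            map(frozenset, true_groups.values())
        ):
            cross_correct += 1

    return {
        "segment_accuracy": accuracy,
        "n_segments": len(seg_ids),
        "per_tree": per_tree,
        "crossover_accuracy": cross_correct / cross_total if cross_total else None,
        "n_crossover_cliques": cross_total,
        "label_mapping": mapping,
    }
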