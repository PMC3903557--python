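"""Transductive label propagation over the weighted segment graph.

With affinity ``W`` (symmetric, nonnegative, zero diagonal) the
normalized operator is ``S = D^{-1/2} W D^{-1/2}``.  Starting from
``Y(0)`` — one-hot rows for the root segments, zero rows elsewhere —
the iteration

    Y(t+1) = alpha * S @ Y(t) + (1 - alpha) * Y(0)

converges for ``alpha`` in (0, 1) to the closed form
``(1 - alpha) (I - alpha S)^{-1} Y(0)``; each segment is then assigned
the tree whose root contributed the largest score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import VesselGraph
from .ordering import OrderingMap, order_segments
from .orientation import EndOrientation, angle_between_segments
from .weights import WeightMatrix

__all__ = [
    "PropagationParams",
    "TreeLabeling",
    "UNASSIGNED",
    "normalize_affinity",
    "propagate_labels",
    "propagate_closed_form",
    "make_seed_matrix",
    "assign_tree_labels",
    "resolve_self_intersections",
]

log = logging.getLogger(__name__)

UNASSIGNED = -1


@dataclass
class PropagationParams:
    alpha: float = 0.9
    epsilon: float = 1e-5
    max_iters: int = 10000

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class TreeLabeling:
    """Final tracing output: segment id → tree id (root segment id)."""

    label: dict[int, int]
    score: dict[int, float]
    tree_of_column: list[int] = field(default_factory=list)  # column → root id

    def trees(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for sid, lab in self.label.items():
            out.setdefault(lab, []).append(sid)
        return out


def normalize_affinity(W: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization ``D^{-1/2} W D^{-1/2}``.

    Zero-degree (isolated) nodes yield zero rows/columns.  For
    ``alpha < 1`` the spectral radius of ``alpha * S`` is below 1, so
    propagation always converges.
    """
    W = np.asarray(W, dtype=float)
    deg = W.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    return dinv[:, None] * W * dinv[None, :]


def make_seed_matrix(ids: list[int], root_ids: set[int]) -> tuple[np.ndarray, list[int]]:
    """One-hot seed matrix Y(0): one column per root, sorted by root id."""
    roots = sorted(root_ids)
    index = {sid: i for i, sid in enumerate(ids)}
    Y0 = np.zeros((len(ids), len(roots)))
    for col, r in enumerate(roots):
        Y0[index[r], col] = 1.0
    return Y0, roots


def propagate_labels(
    S: np.ndarray,
    Y0: np.ndarray,
    params: PropagationParams | None = None,
) -> np.ndarray:
    """Iterate ``Y ← alpha S Y + (1-alpha) Y0`` to convergence.

    Stops when the Frobenius norm of successive iterates drops to
    ``epsilon`` (or at ``max_iters`` with a warning).
    """
    params = params or PropagationParams()
    a = params.alpha
    Y = Y0.copy()
    for _ in range(params.max_iters):
        Y_next = a * (S @ Y) + (1 - a) * Y0
        resid = float(np.linalg.norm(Y_next - Y))
        Y = Y_next
        if resid <= params.epsilon:
            return Y
    warnings.warn(
        f"label propagation hit max_iters={params.max_iters} "
        f"with residual {resid:.3g}",
        RuntimeWarning,
        stacklevel=2,
    )
    return Y


def propagate_closed_form(
    W: np.ndarray,
    Y0: np.ndarray,
    alpha: float = 0.9,
) -> np.ndarray:
    """Closed-form limit ``(1-alpha)(I - alpha S)^{-1} Y0``.

    Serves as the independent oracle for the iterative solver; the
    system is nonsingular for any ``alpha`` in (0, 1).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    S = normalize_affinity(W)
    n = S.shape[0]
    return (1 - alpha) * np.linalg.solve(np.eye(n) - alpha * S, Y0)


def assign_tree_labels(
    Y: np.ndarray,
    wm: WeightMatrix,
    root_ids: set[int],
    tie_tol: float = 1e-12,
) -> TreeLabeling:
    """Argmax decoding of the propagated scores.

    All-zero rows (components without a root) stay UNASSIGNED.  Exact
    ties go to the label of the node's highest-weight neighbour, then
    to the lowest column.  Root rows are forced to their own tree, with
    a warning if propagation disagreed.
    """
    ids = wm.ids
    index = wm.index
    roots = sorted(root_ids)
    label: dict[int, int] = {}
    score: dict[int, float] = {}
    if not roots or Y.shape[1] == 0:
        return TreeLabeling(
            label={sid: UNASSIGNED for sid in ids},
            score={sid: 0.0 for sid in ids},
            tree_of_column=[],
        )

    winner = np.argmax(Y, axis=1)
    for row, sid in enumerate(ids):
        vals = Y[row]
        top = float(vals[winner[row]])
        if top <= 0.0:
            label[sid] = UNASSIGNED
            score[sid] = 0.0
            continue
        tied = np.flatnonzero(vals >= top - tie_tol)
        col = int(winner[row])
        if len(tied) > 1:
            nbr_w = wm.W[row]
            best_nbr = int(np.argmax(nbr_w))
            if nbr_w[best_nbr] > 0:
                nbr_vals = Y[best_nbr]
                nbr_tied = [c for c in tied if nbr_vals[c] >= nbr_vals[tied].max() - tie_tol]
                col = int(min(nbr_tied))
            else:
                col = int(min(tied))
        label[sid] = roots[col]
        score[sid] = top

    for colr, r in enumerate(roots):
        if r in index and label[r] != r:
            log.warning("root segment %d was argmax-assigned to %s; forcing", r, label[r])
            label[r] = r
            score[r] = float(Y[index[r], colr])
    return TreeLabeling(label=label, score=score, tree_of_column=roots)


def resolve_self_intersections(
    tree_ids: list[int],
    vg: VesselGraph,
    orientations: dict[tuple[int, str], EndOrientation],
    root_id: int | None = None,
) -> nx.DiGraph:
    """Turn one labeled tree (possibly self-crossing) into a proper tree.

    Branches of a single tree can cross each other, leaving cycles in
    the labeled subgraph, while downstream consumers (SWC, DIADEM-style
    scoring) require an acyclic parent-child structure.  Edges are
    scored by the junction angle between their two segment ends
    (larger = smoother continuation) and a maximum spanning tree is
    extracted, so at every conflicted junction each segment stays
    attached to the chain it continues most smoothly — the same
    smooth-continuation principle that drives the affinities.  The
    result is rooted at ``root_id`` (default: the subgraph's root
    segment) and returned as a parent→child DiGraph.
    """
    sub = vg.graph.subgraph(tree_ids).copy()
    if root_id is None:
        in_roots = [t for t in tree_ids if t in vg.root_ids]
        root_id = in_roots[0] if in_roots else sorted(tree_ids)[0]

    segset = vg.segments
    for a, b, data in sub.edges(data=True):
        jidx = data["junctions"][0]
        ea = orientations[(a, segset.segments[a].junction_end(jidx))]
        eb = orientations[(b, segset.segments[b].junction_end(jidx))]
        data["theta"] = angle_between_segments(ea, eb)

    if nx.is_forest(sub):
        mst = sub
    else:
        mst = nx.maximum_spanning_tree(sub, weight="theta")

    out = nx.DiGraph()
    out.add_nodes_from(sub.nodes)
    for comp in nx.connected_components(mst):
        start = root_id if root_id in comp else sorted(comp)[0]
        for parent, child in nx.bfs_edges(mst, start):
            out.add_edge(parent, child)
    return out
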