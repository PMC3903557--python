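"""Modified Shreve ordering of vessel segments.

Classic Shreve stream ordering assigns every leaf order 1 and, at each
confluence, the downstream segment the sum of the upstream orders; the
root's order therefore equals the number of leaves (the tree's
*magnitude*).  Vessel networks additionally contain crossovers, so the
scheme is extended clique-wise:

* 3-clique: two ordered members with orders μ1, μ2 → the third gets
  μ1 + μ2;
* 4-clique: two ordered members → *both* remaining members get μ1 + μ2;
* 5-clique: three ordered members → both remaining get μ1 + μ2 + μ3;
* 6-clique: four ordered members → both remaining get the 4-sum.

When no clique can fire (a segment terminating on another vessel, or a
skeletonization artefact), the deadlock is broken at the 3-clique with
a single ordered member whose two unordered segments meet at the
smallest angle — that junction is the most acute, hence the most likely
spurious — and both unordered segments there receive μ + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import EndType, OrderingDeadlockError
from .graph import JunctionClique, VesselGraph
from .orientation import EndOrientation, angle_between_segments

__all__ = ["OrderingMap", "order_segments", "resolve_ordering_deadlock"]

# number of already-ordered members a k-clique needs in order to fire
_FIRE_ARITY = {3: 1 + 1, 4: 2, 5: 3, 6: 4}


@dataclass
class OrderingMap:
    """Segment id → Shreve order μ, with the rule that produced it."""

    order: dict[int, int] = field(default_factory=dict)
    provenance: dict[int, str] = field(default_factory=dict)
    deadlock_cliques: set[int] = field(default_factory=set)  # junction indices

    def __getitem__(self, seg_id: int) -> int:
        return self.order[seg_id]

    def __contains__(self, seg_id: int) -> bool:
        return seg_id in self.order


def _leaf_ids(vg: VesselGraph) -> list[int]:
    """Segments carrying a non-root terminal (END) point."""
    out = []
    for seg in vg.segments:
        if EndType.END in seg.end_types:
            out.append(seg.id)
        elif EndType.ROOT in seg.end_types and seg.junctions == (None, None):
            out.append(seg.id)  # isolated root stroke: trivially a leaf
    return sorted(out)


def _incoming(clique: JunctionClique, om: OrderingMap, roots: set[int]) -> list[int]:
    """Ordered, non-root members available as incoming at this clique.

    Root segments only ever receive an order (propagation stops there),
    so they never count as incoming.
    """
    inc = [m for m in clique.members if m in om and m not in roots]
    # deterministic "earliest ordered first" for over-complete cliques
    inc.sort(key=lambda m: (om.order[m], m))
    return inc


def resolve_ordering_deadlock(
    candidates: list[JunctionClique],
    om: OrderingMap,
    orientations: dict[tuple[int, str], EndOrientation],
    vg: VesselGraph,
) -> tuple[JunctionClique, list[int], int] | None:
    """Pick the deadlocked 3-clique that fires, by smallest junction angle.

    ``candidates`` are 3-cliques with exactly one ordered member of order
    μ.  The clique whose two unordered segments meet at the smallest
    angle fires; both its unordered segments get μ + 1.  Ties break on
    the junction's (row, col).  Returns (clique, unordered members, new
    order) or None when there is no candidate.
    """
    best = None
    for clique in candidates:
        unordered = [m for m in clique.members if m not in om]
        mu = next(om.order[m] for m in clique.members if m in om)
        a, b = unordered
        sa = vg.segments.segments[a]
        sb = vg.segments.segments[b]
        ea = orientations[(a, sa.junction_end(clique.junction_index))]
        eb = orientations[(b, sb.junction_end(clique.junction_index))]
        angle = angle_between_segments(ea, eb)
        key = (angle, clique.point)
        if best is None or key < best[0]:
            best = (key, clique, unordered, mu + 1)
    if best is None:
        return None
    return best[1], best[2], best[3]


def order_segments(
    vg: VesselGraph,
    orientations: dict[tuple[int, str], EndOrientation],
) -> OrderingMap:
    """Assign every segment a modified Shreve order.

    Iterative frontier propagation: leaves get μ = 1, cliques fire per
    the arity rules above, and deadlocks are broken by the smallest-
    angle rule.  Raises :class:`OrderingDeadlockError` when unordered
    segments remain and no rule applies (e.g. a rootless cycle).
    """
    om = OrderingMap()
    roots = set(vg.root_ids)
    for leaf in _leaf_ids(vg):
        om.order[leaf] = 1
        om.provenance[leaf] = "LEAF"

    all_ids = set(vg.graph.nodes)
    cliques = [c for c in vg.cliques if c.size >= 3]
    fired: set[int] = set()

    while len(om.order) < len(all_ids):
        progress = False
        for clique in cliques:
            if clique.junction_index in fired:
                continue
            unordered = [m for m in clique.members if m not in om]
            if not unordered:
                fired.add(clique.junction_index)  # cycle reached it first
                continue
            need = _FIRE_ARITY.get(clique.size, clique.size - 2)
            inc = _incoming(clique, om, roots)
            if len(inc) < need:
                continue
            mu = sum(om.order[m] for m in inc[:need])
            tag = f"CLIQUE{clique.size}"
            for m in unordered:
                om.order[m] = mu
                om.provenance[m] = tag
            fired.add(clique.junction_index)
            progress = True
        if progress:
            continue

        # deadlock: 3-cliques with exactly one ordered, non-root member
        candidates = [
            c
            for c in cliques
            if c.size == 3
            and c.junction_index not in fired
            and sum(1 for m in c.members if m in om) == 1
            and all(m not in roots for m in c.members if m in om)
        ]
        pick = resolve_ordering_deadlock(candidates, om, orientations, vg)
        if pick is not None:
            clique, unordered, mu = pick
            for m in unordered:
                om.order[m] = mu
                om.provenance[m] = "DEADLOCK"
            om.deadlock_cliques.add(clique.junction_index)
            fired.add(clique.junction_index)
            continue

        # segments in no clique at all (isolated strokes) default to 1
        stuck = sorted(all_ids - set(om.order))
        loose = [
            s for s in stuck if vg.segments.segments[s].junctions == (None, None)
        ]
        if loose:
            for s in loose:
                om.order[s] = 1
                om.provenance[s] = "LEAF"
            continue

        # residual rule: near roots, a clique may hold ordered members the
        # main rules cannot use (root segments, or more ordered members
        # than the arity allows next to fewer unordered ones); resume by
        # giving the unordered members max(order in clique) + 1
        residual = None
        for clique in vg.cliques:  # all junctions, including 2-member ones
            if clique.junction_index in fired:
                continue
            unordered = [m for m in clique.members if m not in om]
            ordered = [m for m in clique.members if m in om]
            if unordered and ordered:
                key = clique.point
                if residual is None or key < residual[0]:
                    residual = (key, clique, unordered, ordered)
        if residual is None:
            # leafless component (e.g. two vessels terminating on each
            # other): seed its root segments with order 1 and resume
            seeded = False
            import networkx as nx

            for comp in nx.connected_components(vg.graph):
                if any(m in om for m in comp):
                    continue
                seeds = sorted(comp & roots) or [min(comp)]
                for s in seeds:
                    om.order[s] = 1
                    om.provenance[s] = "SEED"
                    seeded = True
            if seeded:
                continue
            raise OrderingDeadlockError(
                f"cannot order segments {stuck}; stuck junctions remain"
            )
        _, clique, unordered, ordered = residual
        mu = max(om.order[m] for m in ordered) + 1
        for m in unordered:
            om.order[m] = mu
            om.provenance[m] = "RESIDUAL"
        fired.add(clique.junction_index)
    return om
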