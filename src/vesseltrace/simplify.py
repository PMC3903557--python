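"""Per-clique edge pruning guided by segment ordering.

Within a clique the members attaining the highest Shreve order are the
topologically senior ones (closer to the root).  Simplification keeps
only edges between the senior set and the rest — the complete bipartite
set V_CH × V_CNH — discarding sibling edges that would let labels leak
between branches that merely touch at the junction.
"""

from __future__ import annotations

import logging

from .graph import VesselGraph
from .ordering import OrderingMap

__all__ = ["simplify_graph"]

log = logging.getLogger(__name__)


def simplify_graph(vg: VesselGraph, om: OrderingMap) -> VesselGraph:
    """Replace each clique's edges by its V_CH × V_CNH bipartite set.

    A clique whose members all share the same order (possible only in
    cycles) has an empty V_CNH and keeps its edges unchanged, with a
    warning.  Edges shared by two junctions (loops) survive if either
    junction retains them.  The node set is never changed.
    """
    out = vg.copy()
    g = out.graph

    keep: set[tuple[int, int]] = set()
    drop: set[tuple[int, int]] = set()
    for clique in out.cliques:
        members = clique.members
        if len(members) < 3:
            keep.update(
                tuple(sorted((a, b)))
                for i, a in enumerate(members)
                for b in members[i + 1:]
            )
            continue
        mx = max(om.order[m] for m in members)
        v_ch = [m for m in members if om.order[m] == mx]
        v_cnh = [m for m in members if om.order[m] < mx]
        if not v_cnh:
            log.warning(
                "clique at %s has all members of equal order %d; edges kept",
                clique.point, mx,
            )
            keep.update(
                tuple(sorted((a, b)))
                for i, a in enumerate(members)
                for b in members[i + 1:]
            )
            continue
        for a in v_ch:
            for b in v_cnh:
                keep.add(tuple(sorted((a, b))))
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                e = tuple(sorted((a, b)))
                if e not in keep:
                    drop.add(e)

    for e in drop - keep:
        if g.has_edge(*e):
            g.remove_edge(*e)
    return out
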