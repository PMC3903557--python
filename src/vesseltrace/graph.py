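"""Dual graph construction: segments become nodes, junctions become cliques.

Each junction with ``m`` incident segments contributes a complete
m-clique of edges between those segments (3 ≤ m ≤ 6).  A 3-clique is a
branching or a termination, a 4-clique a simple crossover, and 5/6-
cliques are crossovers coinciding with branchings.  Junctions with more
than six incident segments are outside the method's clique taxonomy and
abort with an explicit error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .core import SegmentSet, UnsupportedJunctionError

__all__ = ["JunctionClique", "VesselGraph", "build_graph", "detect_junction_cliques"]

MAX_CLIQUE_SIZE = 6


@dataclass
class JunctionClique:
    """Segments mutually adjacent at one junction point."""

    point: tuple[float, float]
    members: tuple[int, ...]
    junction_index: int

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class VesselGraph:
    """Undirected segment graph with junction cliques and a root set.

    ``graph`` is a :class:`networkx.Graph` whose nodes are segment ids;
    each edge carries ``junctions``, the list of junction indices at
    which the two segments touch (two entries for a length-2 loop).
    """

    graph: nx.Graph
    cliques: list[JunctionClique]
    root_ids: set[int]
    segments: SegmentSet | None = field(default=None, repr=False)

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def copy(self) -> "VesselGraph":
        return VesselGraph(
            graph=self.graph.copy(),
            cliques=list(self.cliques),
            root_ids=set(self.root_ids),
            segments=self.segments,
        )


def build_graph(segset: SegmentSet, strict: bool = True) -> VesselGraph:
    """Build the undirected dual graph of a segment set.

    Nodes are segments; two segments are joined by an edge iff they
    share a junction.  Segments whose chain meets the same junction at
    both ends (a one-segment loop) contribute no self-loop.

    Junctions with more than six incident segments are outside the
    clique taxonomy: with ``strict=True`` (default) they raise
    :class:`UnsupportedJunctionError`; with ``strict=False`` they are
    kept with a warning and handled downstream by the generalized
    big-clique rules (fire with all-but-two ordered members, group by
    the two top orders) — expect degraded accuracy there.
    """
    import logging

    g = nx.Graph()
    g.add_nodes_from(sorted(s.id for s in segset))

    cliques: list[JunctionClique] = []
    for jidx, junc in enumerate(segset.junctions):
        members = tuple(sorted(set(junc.members)))
        if not members:
            continue
        if len(members) > MAX_CLIQUE_SIZE:
            if strict:
                raise UnsupportedJunctionError(
                    f"junction at {junc.point} has {len(members)} incident "
                    f"segments; at most {MAX_CLIQUE_SIZE} are supported"
                )
            logging.getLogger(__name__).warning(
                "junction at %s has %d incident segments; using generalized "
                "big-clique rules", junc.point, len(members)
            )
        cliques.append(JunctionClique(point=junc.point, members=members, junction_index=jidx))
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if g.has_edge(a, b):
                    g.edges[a, b]["junctions"].append(jidx)
                else:
                    g.add_edge(a, b, junctions=[jidx])

    cliques.sort(key=lambda c: c.point)
    return VesselGraph(graph=g, cliques=cliques, root_ids=set(segset.root_ids), segments=segset)


def detect_junction_cliques(vg: VesselGraph) -> list[JunctionClique]:
    """Junction cliques of size ≥ 3, sorted by junction point."""
    return [c for c in vg.cliques if c.size >= 3]
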