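"""Affinity (weight) matrix construction from junction geometry.

The affinity between two segments sharing a junction encodes how likely
they are to belong to the same vessel tree, judged purely from local
orientations:

* 3-cliques: a standard branching rewards smooth continuations through
  ``exp(-f1(theta))``.  A clique created by one vessel terminating on
  another (or by a mis-skeletonized crossover) instead rewards the
  better-aligned of the two through-pairs and damps the other by the
  sign-flipped exponent.
* 4-cliques (simple crossovers): of the three ways to pair the four
  entry points, exactly one pairing's chords cross inside their convex
  hull — that pairing identifies which segments pass through each
  other; those pairs get ``exp(-f2)``, the rest ``exp(-f3)``.
* 5/6-cliques (crossover at a branching): the two highest-order
  segments seed two groups, remaining members join the seed they
  continue more smoothly; within-group edges get ``exp(-f1)``, cross-
  group edges the damped ``exp(+f1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .core import SegmentSet
from .graph import JunctionClique, VesselGraph
from .ordering import OrderingMap
from .orientation import (
    EndOrientation,
    WeightParams,
    angle_between_segments,
    eval_f1,
    eval_f2,
    eval_f3,
)

__all__ = [
    "ThreeCliqueCase",
    "WeightMatrix",
    "classify_three_clique",
    "weight_three_clique",
    "weight_four_clique",
    "weight_five_six_clique",
    "chord_pairing",
    "assemble_weight_matrix",
]

log = logging.getLogger(__name__)


class ThreeCliqueCase(Enum):
    CASE_A = "branching"          # ordinary bifurcation, all one tree
    CASE_B = "termination"        # one vessel ends on another
    CASE_C = "split_crossover"    # mis-skeletonized 4-clique


@dataclass
class WeightMatrix:
    """Symmetric nonnegative affinity over segments, zero diagonal."""

    ids: list[int]                 # segment ids, row/col order
    W: np.ndarray                  # n x n
    edge_records: list[dict] = field(default_factory=list)

    @property
    def index(self) -> dict[int, int]:
        return {sid: i for i, sid in enumerate(self.ids)}


def _end_orientation_at(
    segset: SegmentSet,
    orientations: dict[tuple[int, str], EndOrientation],
    seg_id: int,
    junction_index: int,
) -> EndOrientation:
    end = segset.segments[seg_id].junction_end(junction_index)
    return orientations[(seg_id, end)]


def _theta(segset, orientations, a, b, jidx) -> float:
    return angle_between_segments(
        _end_orientation_at(segset, orientations, a, jidx),
        _end_orientation_at(segset, orientations, b, jidx),
    )


def classify_three_clique(
    clique: JunctionClique,
    om: OrderingMap,
    segset: SegmentSet,
    params: WeightParams | None = None,
) -> tuple[ThreeCliqueCase, dict]:
    """Classify a 3-clique and identify its roles.

    A clique that needed the deadlock rule during ordering is not an
    ordinary branching: its two deadlock-ordered members are the
    through-vessel halves (i, j) and the third member (k) either
    terminates there (case B) or is the short connector left behind by
    a mis-skeletonized crossover (case C, length ≤ ``c_critical``).
    Returns the case plus a role dict (``i``/``j``/``k`` for B/C).
    """
    params = params or WeightParams()
    if clique.junction_index not in om.deadlock_cliques:
        return ThreeCliqueCase.CASE_A, {}
    by_order = sorted(clique.members, key=lambda m: (-om.order[m], m))
    i, j = by_order[0], by_order[1]
    k = by_order[2]
    # the connector of a mis-skeletonized crossover runs junction-to-
    # junction; the shortest such member decides case C
    connector_lens = [
        segset.segments[m].length
        for m in clique.members
        if None not in segset.segments[m].junctions
    ]
    case = (
        ThreeCliqueCase.CASE_C
        if connector_lens and min(connector_lens) <= params.c_critical
        else ThreeCliqueCase.CASE_B
    )
    return case, {"i": i, "j": j, "k": k}


def weight_three_clique(
    clique: JunctionClique,
    case: ThreeCliqueCase,
    roles: dict,
    segset: SegmentSet,
    orientations,
    surviving: set[tuple[int, int]],
    params: WeightParams | None = None,
) -> dict[tuple[int, int], tuple[float, float, str]]:
    """Weights for the edges of one 3-clique.

    Case A: every surviving edge (a, b) gets ``exp(-f1(theta_ab))``.
    Case B/C: the clique is not an ordinary branching — one vessel
    terminates on another, or a crossover was split in two.  The two
    deadlock-ordered members are the vessel that continues through the
    junction: their edge is rewarded with ``exp(-f1(theta))`` *even
    when simplification removed it from the graph*, while the worse-
    aligned of the two remaining pairs is damped by the sign-flipped
    ``exp(+f1(psi))`` and the other keeps the case-A weight.
    Returns {(a, b): (weight, theta, rule)}.
    """
    params = params or WeightParams()
    jidx = clique.junction_index
    out: dict[tuple[int, int], tuple[float, float, str]] = {}

    def edge(a, b):
        return tuple(sorted((a, b)))

    assigned: set[tuple[int, int]] = set()
    if case in (ThreeCliqueCase.CASE_B, ThreeCliqueCase.CASE_C):
        pairs = {
            edge(a, b): _theta(segset, orientations, a, b, jidx)
            for a, b in _clique_edges(clique)
        }
        through = edge(roles["i"], roles["j"])
        out[through] = (np.exp(-eval_f1(pairs[through], params)), pairs[through],
                        f"3{case.name}+")
        assigned.add(through)
        worst = min((e for e in pairs if e != through), key=lambda e: pairs[e])
        if worst in surviving:
            out[worst] = (np.exp(eval_f1(pairs[worst], params)), pairs[worst],
                          f"3{case.name}-")
            assigned.add(worst)

    for a, b in _clique_edges(clique):
        e = edge(a, b)
        if e in surviving and e not in assigned:
            theta = _theta(segset, orientations, a, b, jidx)
            out[e] = (np.exp(-eval_f1(theta, params)), theta, "3CASE_A")
    return out


def _clique_edges(clique: JunctionClique):
    m = clique.members
    return [(a, b) for idx, a in enumerate(m) for b in m[idx + 1:]]


def _segments_properly_intersect(p1, p2, p3, p4) -> bool:
    """Closed-segment intersection via orientation tests."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    def on_seg(a, b, c):
        return (
            min(a[0], b[0]) - 1e-12 <= c[0] <= max(a[0], b[0]) + 1e-12
            and min(a[1], b[1]) - 1e-12 <= c[1] <= max(a[1], b[1]) + 1e-12
        )

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    if o1 != o2 and o3 != o4:
        return True
    for a, b, c in ((p1, p2, p3), (p1, p2, p4), (p3, p4, p1), (p3, p4, p2)):
        if orient(a, b, c) == 0 and on_seg(a, b, c):
            return True
    return False


def chord_pairing(points: dict[int, tuple[float, float]]) -> list[tuple[int, int]] | None:
    """Find the pairing of four entry points whose chords cross.

    ``points`` maps the four segment ids to their representative entry
    pixels around the junction.  Of the three pairings of chords,
    returns the unique one whose two chords intersect (inside the
    convex hull of the four points); None when the configuration is
    degenerate or ambiguous.
    """
    ids = sorted(points)
    if len(ids) != 4:
        raise ValueError("chord pairing needs exactly four points")
    a, b, c, d = ids
    pairings = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
    hits = [
        (e1, e2)
        for e1, e2 in pairings
        if _segments_properly_intersect(points[e1[0]], points[e1[1]], points[e2[0]], points[e2[1]])
    ]
    if len(hits) != 1:
        return None
    return [hits[0][0], hits[0][1]]


def weight_four_clique(
    clique: JunctionClique,
    segset: SegmentSet,
    orientations,
    surviving: set[tuple[int, int]],
    params: WeightParams | None = None,
) -> dict[tuple[int, int], tuple[float, float, str]]:
    """Weights for one 4-clique (simple crossover).

    Representative entry points are each member's skeleton pixel at the
    junction; the chord pairing that crosses inside the convex hull
    tells which segments continue through each other.  Favourable pairs
    get ``exp(-f2(theta))``, other surviving edges ``exp(-f3(theta))``.
    Degenerate geometry falls back to pairing each segment with the one
    it meets at the largest angle.
    """
    params = params or WeightParams()
    jidx = clique.junction_index
    entry = {
        m: segset.segments[m].end_pixel(segset.segments[m].junction_end(jidx))
        for m in clique.members
    }
    pairing = chord_pairing(entry)
    if pairing is None:
        log.warning(
            "degenerate 4-clique geometry at %s; using angle-based pairing",
            clique.point,
        )
        remaining = list(clique.members)
        pairing = []
        while remaining:
            a = remaining.pop(0)
            best = max(remaining, key=lambda b: _theta(segset, orientations, a, b, jidx))
            remaining.remove(best)
            pairing.append((a, best))
    favorable = {tuple(sorted(p)) for p in pairing}

    out: dict[tuple[int, int], tuple[float, float, str]] = {}
    for a, b in _clique_edges(clique):
        e = tuple(sorted((a, b)))
        theta = _theta(segset, orientations, a, b, jidx)
        if e in favorable:
            # the through-continuation pairs get their reward even when
            # simplification dropped the edge (both ends same order)
            out[e] = (np.exp(-eval_f2(theta, params)), theta, "4FAV")
        elif e in surviving:
            out[e] = (np.exp(-eval_f3(theta, params)), theta, "4UNFAV")
    return out


def weight_five_six_clique(
    clique: JunctionClique,
    om: OrderingMap,
    segset: SegmentSet,
    orientations,
    surviving: set[tuple[int, int]],
    params: WeightParams | None = None,
) -> dict[tuple[int, int], tuple[float, float, str]]:
    """Weights for a 5- or 6-clique (crossover at a branching point).

    The two members with the largest orders seed two groups (they lie
    on opposite sides of the crossover); every other member joins the
    seed it meets at the larger angle (smoother continuation).  Edges
    within a group get ``exp(-f1(theta))``, across groups the damped
    ``exp(+f1(theta))``.
    """
    params = params or WeightParams()
    jidx = clique.junction_index
    by_order = sorted(clique.members, key=lambda m: (-om.order[m], m))
    top = om.order[by_order[0]]
    second = om.order[by_order[1]]
    if sum(1 for m in clique.members if om.order[m] == top) > 2 or (
        top == second and sum(1 for m in clique.members if om.order[m] == top) > 2
    ):
        log.warning("order tie among >2 members of clique at %s", clique.point)
    seed_i, seed_j = by_order[0], by_order[1]

    group = {seed_i: 0, seed_j: 1}
    for m in clique.members:
        if m in group:
            continue
        ti = _theta(segset, orientations, m, seed_i, jidx)
        tj = _theta(segset, orientations, m, seed_j, jidx)
        group[m] = 0 if ti >= tj else 1

    out: dict[tuple[int, int], tuple[float, float, str]] = {}
    for a, b in _clique_edges(clique):
        e = tuple(sorted((a, b)))
        if e not in surviving:
            continue
        theta = _theta(segset, orientations, a, b, jidx)
        if group[a] == group[b]:
            out[e] = (np.exp(-eval_f1(theta, params)), theta, f"{clique.size}IN")
        else:
            out[e] = (np.exp(eval_f1(theta, params)), theta, f"{clique.size}X")
    return out


def assemble_weight_matrix(
    vg: VesselGraph,
    om: OrderingMap,
    orientations,
    params: WeightParams | None = None,
) -> WeightMatrix:
    """Assemble the symmetric affinity matrix over the simplified graph.

    Every surviving edge receives a weight from its junction's clique
    rule; edges of sub-3-cliques (and any edge somehow left unassigned)
    fall back to ``exp(-f1(theta))`` with a warning.  Edges shared by
    two junctions take the larger of their two assignments.
    """
    params = params or WeightParams()
    segset = vg.segments
    surviving = vg.edges
    ids = vg.node_ids
    index = {sid: i for i, sid in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    records: list[dict] = []
    assigned: dict[tuple[int, int], float] = {}

    def put(e, w, theta, rule, jidx):
        if e in assigned and not np.isclose(assigned[e], w):
            log.debug("edge %s assigned by two junctions; keeping max", e)
            if w <= assigned[e]:
                return
        assigned[e] = w
        records.append(
            {"i": e[0], "j": e[1], "theta_deg": theta, "rule": rule, "weight": w,
             "junction": jidx}
        )

    for clique in vg.cliques:
        if clique.size < 3:
            for a, b in _clique_edges(clique):
                e = tuple(sorted((a, b)))
                if e in surviving:
                    theta = _theta(segset, orientations, a, b, clique.junction_index)
                    put(e, float(np.exp(-eval_f1(theta, params))), theta, "PAIR",
                        clique.junction_index)
            continue
        if clique.size == 3:
            case, roles = classify_three_clique(clique, om, segset, params)
            w3 = weight_three_clique(
                clique, case, roles, segset, orientations, surviving, params
            )
            for e, (w, theta, rule) in w3.items():
                put(e, float(w), theta, rule, clique.junction_index)
        elif clique.size == 4:
            w4 = weight_four_clique(clique, segset, orientations, surviving, params)
            for e, (w, theta, rule) in w4.items():
                put(e, float(w), theta, rule, clique.junction_index)
        else:
            # size 5/6 proper; >6 handled by the same two-group rule
            w56 = weight_five_six_clique(
                clique, om, segset, orientations, surviving, params
            )
            for e, (w, theta, rule) in w56.items():
                put(e, float(w), theta, rule, clique.junction_index)

    missing = surviving - set(assigned)
    for e in sorted(missing):
        a, b = e
        jidxs = vg.graph.edges[a, b].get("junctions", [])
        if jidxs:
            theta = _theta(segset, orientations, a, b, jidxs[0])
        else:  # pragma: no cover - every edge stems from a junction
            theta = 90.0
        log.warning("edge %s not covered by any clique rule; f1 fallback", e)
        put(e, float(np.exp(-eval_f1(theta, params))), theta, "FALLBACK",
            jidxs[0] if jidxs else -1)

    for (a, b), w in assigned.items():
        W[index[a], index[b]] = w
        W[index[b], index[a]] = w
    return WeightMatrix(ids=ids, W=W, edge_records=records)
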