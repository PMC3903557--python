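"""Label propagation: normalization, iteration vs closed form, decoding."""

from __future__ import annotations

import numpy as np
import pytest

from vesseltrace.propagate import (
    PropagationParams,
    UNASSIGNED,
    assign_tree_labels,
    make_seed_matrix,
    normalize_affinity,
    propagate_closed_form,
    propagate_labels,
    resolve_self_intersections,
)
from vesseltrace.weights import WeightMatrix


def random_symmetric_affinity(rng, n, density=0.4):
    W = rng.uniform(0, 1, (n, n))
    mask = rng.uniform(0, 1, (n, n)) < density
    W = np.triu(W * mask, 1)
    W = W + W.T
    return W


class TestNormalize:
    def test_unit_degrees_identity(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(normalize_affinity(W), W)

    def test_star_normalization(self):
        # hub 0 with 3 unit-weight leaves: spokes become 1/sqrt(3)
        W = np.zeros((4, 4))
        W[0, 1:] = 1.0
        W[1:, 0] = 1.0
        S = normalize_affinity(W)
        assert np.allclose(S[0, 1:], 1 / np.sqrt(3))

    def test_isolated_node_zero_row(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        S = normalize_affinity(W)
        assert np.all(S[2] == 0) and np.all(S[:, 2] == 0)

    def test_spectral_radius_below_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            W = random_symmetric_affinity(rng, 12)
            S = normalize_affinity(W)
            rho = np.max(np.abs(np.linalg.eigvalsh(S)))
            assert 0.9 * rho < 1.0 + 1e-9


class TestPropagation:
    def test_two_node_closed_form_match(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        Y0 = np.array([[1.0], [0.0]])
        S = normalize_affinity(W)
        it = propagate_labels(S, Y0, PropagationParams(alpha=0.9, epsilon=1e-10))
        cf = propagate_closed_form(W, Y0, 0.9)
        assert np.max(np.abs(it - cf)) < 1e-6

    def test_zero_seed_stays_zero(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.all(propagate_closed_form(W, np.zeros((2, 1)), 0.9) == 0)

    def test_isolated_root_row(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        Y0 = np.zeros((3, 1))
        Y0[2, 0] = 1.0  # isolated root
        out = propagate_closed_form(W, Y0, 0.9)
        assert out[2, 0] == pytest.approx(0.1)
        assert np.all(out[:2] == 0)

    def test_iterative_matches_closed_form_on_random_graphs(self):
        """Oracle equivalence on 100 random affinities (n <= 30)."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(3, 31))
            W = random_symmetric_affinity(rng, n)
            c = int(rng.integers(1, 4))
            Y0 = np.zeros((n, c))
            for col, row in enumerate(rng.choice(n, size=c, replace=False)):
                Y0[row, col] = 1.0
            S = normalize_affinity(W)
            it = propagate_labels(S, Y0, PropagationParams(alpha=0.9, epsilon=1e-8))
            cf = propagate_closed_form(W, Y0, 0.9)
            assert np.max(np.abs(it - cf)) <= 1e-6

    def test_residual_eventually_geometric(self):
        rng = np.random.default_rng(5)
        W = random_symmetric_affinity(rng, 15)
        S = normalize_affinity(W)
        Y0 = np.zeros((15, 1)); Y0[0, 0] = 1.0
        alpha = 0.9
        rho = np.max(np.abs(np.linalg.eigvalsh(S)))
        Y = Y0.copy()
        resids = []
        for _ in range(60):
            Yn = alpha * S @ Y + (1 - alpha) * Y0
            resids.append(np.linalg.norm(Yn - Y))
            Y = Yn
        ratios = np.array(resids[40:]) / np.array(resids[39:-1])
        assert np.all(ratios <= alpha * rho + 1e-9)

    def test_symmetric_barbell_tie(self):
        # path 0-1-2 with roots at 0 and 2: middle node scores equal
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
        Y0 = np.zeros((3, 2)); Y0[0, 0] = 1.0; Y0[2, 1] = 1.0
        out = propagate_closed_form(W, Y0, 0.9)
        assert abs(out[1, 0] - out[1, 1]) < 1e-9


class TestAssignment:
    def _wm(self, W):
        return WeightMatrix(ids=list(range(len(W))), W=np.asarray(W, float))

    def test_two_triangles_labeled_by_component_root(self):
        W = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            W[a, b] = W[b, a] = 1.0
        wm = self._wm(W)
        Y0, roots = make_seed_matrix(wm.ids, {0, 3})
        Y = propagate_closed_form(W, Y0, 0.9)
        lab = assign_tree_labels(Y, wm, {0, 3})
        assert all(lab.label[i] == 0 for i in (0, 1, 2))
        assert all(lab.label[i] == 3 for i in (3, 4, 5))

    def test_rootless_component_unassigned(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        wm = self._wm(W)
        Y0, _ = make_seed_matrix(wm.ids, {0})
        Y = propagate_closed_form(W, Y0, 0.9)
        lab = assign_tree_labels(Y, wm, {0})
        assert lab.label[2] == UNASSIGNED and lab.label[3] == UNASSIGNED

    def test_labels_subset_of_roots(self):
        rng = np.random.default_rng(9)
        W = random_symmetric_affinity(rng, 20)
        wm = self._wm(W)
        roots = {1, 5, 12}
        Y0, _ = make_seed_matrix(wm.ids, roots)
        Y = propagate_closed_form(W, Y0, 0.9)
        lab = assign_tree_labels(Y, wm, roots)
        assert set(lab.label.values()) - {UNASSIGNED} <= roots


class TestSelfIntersection:
    def test_tree_without_cycles_unchanged(self, y_mask_and_disk):
        from vesseltrace.graph import build_graph
        from vesseltrace.ordering import order_segments
        from vesseltrace.orientation import segment_orientations
        from vesseltrace.simplify import simplify_graph
        from vesseltrace.skeletonize import extract_segments, skeletonize_mask

        mask, disk = y_mask_and_disk
        segs = extract_segments(skeletonize_mask(mask), disk)
        vg = build_graph(segs)
        ori = segment_orientations(segs)
        sg = simplify_graph(vg, order_segments(vg, ori))
        out = resolve_self_intersections(list(sg.graph.nodes), sg, ori)
        assert set(out.nodes) == set(sg.graph.nodes)
        assert out.number_of_edges() == sg.graph.number_of_edges()
        assert {tuple(sorted(e)) for e in out.edges} == sg.edges

    def test_self_crossing_tree_becomes_acyclic(self):
        """Cycle-detection oracle on random self-intersecting trees."""
        import networkx as nx
        from vesseltrace.core import EndType, Junction, Segment, SegmentSet
        from vesseltrace.graph import build_graph
        from vesseltrace.orientation import segment_orientations

        rng = np.random.default_rng(17)
        for _ in range(100):
            # a ladder of 4-cliques: segments forming cycles in the dual
            n_j = int(rng.integers(2, 5))
            segments = {}
            junctions = []
            sid = 0
            prev_pair = None
            for j in range(n_j):
                junctions.append(Junction(point=(50.0, 20.0 + 30 * j),
                                          pixels=[(50, 20 + 30 * j)]))
            for j in range(n_j):
                for arm in range(2):
                    jf = j - 1 if j > 0 else None
                    pix = [(50 + (arm * 2 - 1) * (5 + i), 20 + 30 * (j - 1) + 15 + i)
                           for i in range(8)]
                    et0 = EndType.BRANCH if jf is not None else (
                        EndType.ROOT if sid == 0 else EndType.END)
                    segments[sid] = Segment(
                        id=sid, pixels=pix,
                        end_types=(et0, EndType.BRANCH),
                        radii=[1.0] * len(pix), junctions=(jf, j),
                    )
                    if jf is not None:
                        junctions[jf].members.append(sid)
                    junctions[j].members.append(sid)
                    sid += 1
            segset = SegmentSet(segments=segments, junctions=junctions,
                                root_ids={0})
            vg = build_graph(segset, strict=False)
            if nx.is_forest(vg.graph):
                continue
            ori = segment_orientations(segset)
            out = resolve_self_intersections(list(vg.graph.nodes), vg, ori)
            assert nx.is_directed_acyclic_graph(out)
            assert set(out.nodes) == set(vg.graph.nodes)
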