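"""Skeleton extraction, pixel taxonomy, segments, disk detection, spurs."""

from __future__ import annotations

import numpy as np
import pytest
from skimage import draw

from vesseltrace.core import (
    EmptySkeletonError,
    EndType,
    NoRootsError,
    PixelClass,
    Segment,
    Junction,
    SegmentSet,
)
from vesseltrace.skeletonize import (
    detect_optic_disk,
    extract_segments,
    remove_spurious_segments,
    skeletonize_mask,
)


def brute_force_nearest_background(mask):
    """Exhaustive nearest-background distance per pixel (the radius oracle)."""
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape)
    for r, c in np.argwhere(mask):
        out[r, c] = np.sqrt(((bg - [r, c]) ** 2).sum(axis=1).min())
    return out


class TestSkeletonizeMask:
    def test_thin_line_is_its_own_skeleton(self):
        mask = np.zeros((5, 11), dtype=bool)
        mask[2, 1:10] = True
        sm = skeletonize_mask(mask)
        assert np.array_equal(sm.skeleton, mask)
        classes = sm.pixel_class[2, 1:10]
        assert classes[0] == PixelClass.TERMINAL.value
        assert classes[-1] == PixelClass.TERMINAL.value
        assert np.all(classes[1:-1] == PixelClass.BODY.value)
        assert np.allclose(sm.radius[mask], 1.0)

    def test_plus_sign_center_is_branching(self):
        mask = np.zeros((11, 11), dtype=bool)
        mask[5, 1:10] = True
        mask[1:10, 5] = True
        sm = skeletonize_mask(mask)
        assert sm.pixel_class[5, 5] == PixelClass.BRANCHING.value
        assert (sm.pixel_class == PixelClass.TERMINAL.value).sum() == 4

    def test_rectangle_midline_and_radius_oracle(self):
        mask = np.zeros((15, 37), dtype=bool)
        mask[3:12, 3:34] = True  # 9 x 31 filled rectangle
        sm = skeletonize_mask(mask)
        # the central part of the midline row survives thinning
        mid = 7
        assert sm.skeleton[mid, 15:22].all()
        oracle = brute_force_nearest_background(mask)
        on = sm.skeleton
        assert np.allclose(sm.radius[on], oracle[on], atol=1e-9)

    def test_radius_equals_brute_force_on_random_blobs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            mask = np.zeros((28, 28), dtype=bool)
            for _ in range(rng.integers(1, 4)):
                rr, cc = draw.disk(
                    (rng.integers(6, 22), rng.integers(6, 22)),
                    rng.integers(2, 6), shape=mask.shape,
                )
                mask[rr, cc] = True
            if not mask.any():
                continue
            sm = skeletonize_mask(mask)
            oracle = brute_force_nearest_background(mask)
            assert np.allclose(sm.radius[sm.skeleton], oracle[sm.skeleton], atol=1e-9)

    def test_all_zero_mask_raises(self):
        with pytest.raises(EmptySkeletonError):
            skeletonize_mask(np.zeros((5, 5), dtype=bool))

    def test_no_2x2_block(self, x_mask_and_disk):
        mask, _ = x_mask_and_disk
        sm = skeletonize_mask(mask)
        s = sm.skeleton
        quad = s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]
        assert not quad.any()

    @pytest.mark.parametrize("transform", ["transpose", "rot90"])
    def test_class_counts_stable_under_symmetry(self, y_mask_and_disk, transform):
        mask, _ = y_mask_and_disk
        sm = skeletonize_mask(mask)
        tmask = mask.T if transform == "transpose" else np.rot90(mask)
        sm_t = skeletonize_mask(tmask)
        for cls in PixelClass:
            assert (sm.pixel_class == cls.value).sum() == (
                sm_t.pixel_class == cls.value
            ).sum()


class TestExtractSegments:
    def test_y_shape(self, y_mask_and_disk):
        mask, disk = y_mask_and_disk
        segs = extract_segments(skeletonize_mask(mask), disk)
        assert len(segs) == 3
        assert len(segs.root_ids) == 1
        assert len(segs.junctions) == 1
        assert len(segs.junctions[0].members) == 3

    def test_x_shape(self, x_mask_and_disk):
        mask, disk = x_mask_and_disk
        segs = extract_segments(skeletonize_mask(mask), disk)
        segs = remove_spurious_segments(segs)
        assert len(segs) == 4
        assert len(segs.root_ids) == 2

    def test_segment_cover_invariant(self, x_mask_and_disk):
        mask, disk = x_mask_and_disk
        sm = skeletonize_mask(mask)
        segs = extract_segments(sm, disk)
        covered = set()
        for s in segs:
            covered.update(s.pixels)
        for j in segs.junctions:
            covered.update(j.pixels)
        skel_set = {tuple(p) for p in np.argwhere(sm.skeleton)}
        assert covered == skel_set

    def test_no_terminal_in_disk_raises(self, y_mask_and_disk):
        mask, _ = y_mask_and_disk
        empty_disk = np.zeros_like(mask)
        empty_disk[:2, :2] = True  # far from any terminal
        with pytest.raises(NoRootsError):
            extract_segments(skeletonize_mask(mask), empty_disk)

    def test_chain_pixels_are_8_connected(self, x_mask_and_disk):
        mask, disk = x_mask_and_disk
        segs = extract_segments(skeletonize_mask(mask), disk)
        for s in segs:
            for p, q in zip(s.pixels[:-1], s.pixels[1:]):
                assert max(abs(p[0] - q[0]), abs(p[1] - q[1])) == 1


class TestDetectOpticDisk:
    def test_bright_circle_found(self):
        rng = np.random.default_rng(1)
        img = rng.normal(10, 1, (120, 120))
        rr, cc = draw.disk((40, 70), 12)
        img[rr, cc] += 60
        region = detect_optic_disk(img)
        assert region[40, 70]

    def test_uniform_image_raises(self):
        with pytest.raises(ValueError, match="disk mask"):
            detect_optic_disk(np.ones((50, 50)))


def _spur_segment_set(beta_deg, conn_len):
    """Hand-built connector between two 3-way junctions.

    The connector runs horizontally; at each junction the two flanking
    arms leave at ±beta_deg from the connector's line, so the spur's
    flanking line angle is beta_deg.
    """
    import math

    def arm(start, angle_deg, n=20, sign=1):
        d = np.array([math.sin(math.radians(angle_deg)),
                      sign * math.cos(math.radians(angle_deg))])
        return [tuple(np.rint(np.array(start, float) + i * d).astype(int))
                for i in range(1, n + 1)]

    j1 = (50, 50)
    j2 = (50, 50 + conn_len + 1)
    conn = [(50, c) for c in range(51, 51 + conn_len)]
    segments = {}
    junctions = [Junction(point=j1, pixels=[j1]), Junction(point=j2, pixels=[j2])]

    def add(sid, pixels, jf, jl, et):
        segments[sid] = Segment(id=sid, pixels=pixels, end_types=et,
                                radii=[1.0] * len(pixels), junctions=(jf, jl))
        for j in {x for x in (jf, jl) if x is not None}:
            junctions[j].members.append(sid)

    add(0, arm(j1, -beta_deg, sign=-1)[::-1], None, 0, (EndType.END, EndType.BRANCH))
    add(1, arm(j1, beta_deg, sign=-1)[::-1], None, 0, (EndType.END, EndType.BRANCH))
    add(2, conn, 0, 1, (EndType.BRANCH, EndType.BRANCH))
    add(3, arm(j2, -beta_deg), 1, None, (EndType.BRANCH, EndType.END))
    add(4, arm(j2, beta_deg), 1, None, (EndType.BRANCH, EndType.END))
    return SegmentSet(segments=segments, junctions=junctions, root_ids=set(),
                      shape=(120, 120))


class TestSpurRemoval:
    @pytest.mark.parametrize(
        "beta,length,removed",
        [(50, 8, True), (50, 15, False), (85, 8, False)],
        ids=["short-acute-removed", "long-kept", "wide-angle-kept"],
    )
    def test_truth_table(self, beta, length, removed):
        segset = _spur_segment_set(beta, length)
        out = remove_spurious_segments(segset, beta_critical=70, c_critical=10)
        assert (2 not in out.segments) == removed
        if removed:
            # the two 3-way junctions collapsed into one 4-way junction
            assert len(out.junctions) == 1
            assert len(out.junctions[0].members) == 4

    def test_idempotent(self):
        segset = _spur_segment_set(50, 8)
        once = remove_spurious_segments(segset, 70, 10)
        twice = remove_spurious_segments(once, 70, 10)
        assert set(once.segments) == set(twice.segments)
        assert len(once.junctions) == len(twice.junctions)

    def test_x_crossing_connector_removed(self, x_mask_and_disk):
        mask, disk = x_mask_and_disk
        segs = extract_segments(skeletonize_mask(mask), disk)
        out = remove_spurious_segments(segs)
        assert len(out) == 4
        assert max(len(j.members) for j in out.junctions) == 4
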