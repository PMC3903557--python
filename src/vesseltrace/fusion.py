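"""Fusing complementary binary segmentations and bridging broken branches.

Upstream segmenters have complementary failure modes: a high-F1 mask is
clean but drops thin branches and merges close parallel vessels; a
high-recall mask keeps thin branches at the cost of noise; an
unsupervised (wavelet-style) mask keeps parallel vessels separated.
Fusion starts from the high-F1 skeleton and swaps out segments by their
calibre: segments thinner than the image's mean segment diameter d_m
are replaced from the high-recall skeleton, segments thicker than
d_m + 1 SD from the unsupervised one, preferring thin-and-long
candidates and preserving junction connectivity by snapping replacement
endpoints onto the retained skeleton.

Separately, small skeleton components that remain disconnected are
bridged by fitting a cubic in the component's principal-axis frame and
extending it pixel-by-pixel until it touches another component; bridged
pixels interpolate their radii from the two sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw, morphology

from .core import SegmentSet, SkeletonMap
from .skeletonize import extract_segments, skeletonize_mask

__all__ = [
    "segment_diameters",
    "fuse_segmentations",
    "reconnect_disconnected_branches",
    "FusionResult",
]

log = logging.getLogger(__name__)


@dataclass
class FusionResult:
    skeleton: np.ndarray          # bool
    radius: np.ndarray            # float, valid on skeleton
    replaced_thin: list[int]      # f1 segment ids swapped from the recall mask
    replaced_thick: list[int]     # f1 segment ids swapped from the unsupervised mask


def segment_diameters(mask: np.ndarray) -> tuple[dict[int, float], float, SegmentSet]:
    """Median diameter per skeleton segment and their mean d_m.

    Per skeleton point the diameter is twice the Euclidean distance to
    the nearest background pixel; a segment's diameter is the median of
    its point diameters, and d_m averages the segment medians.
    """
    skel = skeletonize_mask(mask)
    segset = extract_segments(skel, disk=None, require_roots=False)
    if not len(segset):
        raise ValueError("mask skeletonized to no segments")
    med = {s.id: float(np.median([2.0 * r for r in s.radii])) for s in segset}
    d_m = float(np.mean(list(med.values())))
    return med, d_m, segset


def _band(pixels, shape, tol=2):
    m = np.zeros(shape, dtype=bool)
    for p in pixels:
        m[p] = True
    return morphology.dilation(m, morphology.disk(tol))


def _candidates(band: np.ndarray, donor: SegmentSet, min_overlap: int = 2):
    """Donor segments corresponding to a tolerance band.

    The best-overlapping donor segment is always selected; further
    segments join when at least half their own length lies in the band
    (two parallel thin vessels replacing one merged thick one).  Sorted
    by (overlap, length) so thin-and-long candidates win ties.
    """
    scored = []
    for seg in donor:
        inside = sum(1 for p in seg.pixels if band[p])
        if inside >= min_overlap:
            scored.append((inside, seg.length, seg.id))
    scored.sort(reverse=True)
    if not scored:
        return []
    out = [scored[0][2]]
    for inside, length, sid in scored[1:]:
        if inside >= max(min_overlap, length // 2):
            out.append(sid)
    return out


def _snap_endpoints(pixels: set, retained: np.ndarray, max_dist: int = 3) -> set:
    """Connect loose chain endpoints to the nearest retained pixel."""
    if not pixels or not retained.any():
        return pixels
    ret_pts = np.argwhere(retained)
    added = set()
    for p in list(pixels):
        d = np.abs(ret_pts - np.array(p)).max(axis=1)
        i = int(np.argmin(d))
        if 1 < d[i] <= max_dist:
            rr, cc = draw.line(p[0], p[1], int(ret_pts[i][0]), int(ret_pts[i][1]))
            added.update(zip(map(int, rr), map(int, cc)))
    return pixels | added


def fuse_segmentations(
    mask_f1: np.ndarray,
    mask_recall: np.ndarray,
    mask_iuwt: np.ndarray,
    band_tol: int = 2,
    snap_dist: int = 3,
) -> FusionResult:
    """Calibre-guided fusion of three binary segmentations.

    Thin segments (median diameter < d_m) of the high-F1 skeleton are
    replaced by the overlapping segments of the high-recall skeleton;
    thick segments (> d_m + 1 SD) by those of the unsupervised
    skeleton.  When no corresponding donor segment exists the original
    is kept.  With three identical inputs the result equals the high-F1
    skeleton (every segment is replaced by itself).
    """
    shapes = {np.asarray(m).shape for m in (mask_f1, mask_recall, mask_iuwt)}
    if len(shapes) != 1:
        raise ValueError("the three masks must share dimensions")

    med, d_m, segs_f1 = segment_diameters(mask_f1)
    sd = float(np.std(list(med.values())))
    _, _, segs_recall = segment_diameters(mask_recall)
    _, _, segs_iuwt = segment_diameters(mask_iuwt)
    shape = np.asarray(mask_f1).shape

    dist = {
        "f1": ndimage.distance_transform_edt(np.asarray(mask_f1) > 0),
        "recall": ndimage.distance_transform_edt(np.asarray(mask_recall) > 0),
        "iuwt": ndimage.distance_transform_edt(np.asarray(mask_iuwt) > 0),
    }

    keep: set = set()
    origin: dict = {}
    replaced_thin: list[int] = []
    replaced_thick: list[int] = []
    swaps: list[tuple[int, str, SegmentSet]] = []
    for seg in segs_f1:
        if med[seg.id] < d_m:
            swaps.append((seg.id, "recall", segs_recall))
        elif sd > 0 and med[seg.id] > d_m + sd:
            swaps.append((seg.id, "iuwt", segs_iuwt))
        else:
            for p in seg.pixels:
                keep.add(p)
                origin[p] = "f1"
    # junction pixels of the f1 skeleton are structural; always retained
    for junc in segs_f1.junctions:
        for p in junc.pixels:
            keep.add(p)
            origin[p] = "f1"

    for sid, donor_name, donor in swaps:
        seg = segs_f1.segments[sid]
        band = _band(seg.pixels, shape, band_tol)
        cand = _candidates(band, donor)
        if not cand:
            log.warning("no donor segment for segment %d; keeping original", sid)
            for p in seg.pixels:
                keep.add(p)
                origin[p] = "f1"
            continue
        (replaced_thin if donor_name == "recall" else replaced_thick).append(sid)
        # a corresponding donor segment is taken whole — that is how a
        # branch broken in the primary mask gets its full extent back
        new_pix = set()
        for cid in cand:
            new_pix.update(donor.segments[cid].pixels)
        retained = np.zeros(shape, dtype=bool)
        for p in keep:
            retained[p] = True
        new_pix = _snap_endpoints(new_pix, retained, snap_dist)
        for p in new_pix:
            keep.add(p)
            origin.setdefault(p, donor_name)

    skeleton = np.zeros(shape, dtype=bool)
    radius = np.zeros(shape, dtype=float)
    for p in keep:
        skeleton[p] = True
        radius[p] = dist[origin.get(p, "f1")][p]
    return FusionResult(skeleton=skeleton, radius=radius,
                        replaced_thin=replaced_thin, replaced_thick=replaced_thick)


def _fit_and_extend(pts: np.ndarray, budget: int) -> tuple[np.ndarray, np.ndarray]:
    """Cubic fit in the principal-axis frame; extension directions/rays.

    Returns, for each of the two ends, the sequence of extension points
    (float coordinates, 1 px apart) following the fitted curve.
    """
    mean = pts.mean(axis=0)
    centered = pts - mean
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis, ortho = vt[0], vt[1] if vt.shape[0] > 1 else np.array([-vt[0][1], vt[0][0]])
    u = centered @ axis
    v = centered @ ortho
    deg = 3 if len(pts) >= 4 else 1
    coeff = np.polyfit(u, v, deg)
    poly = np.poly1d(coeff)
    dpoly = poly.deriv()

    rays = []
    for end, sign in ((u.max(), 1.0), (u.min(), -1.0)):
        ray = []
        uu = end
        for _ in range(budget):
            slope = float(dpoly(uu))
            du = sign / np.hypot(1.0, slope)
            uu = uu + du
            point = mean + uu * axis + float(poly(uu)) * ortho
            ray.append(point)
        rays.append(np.array(ray))
    return rays[0], rays[1]


def reconnect_disconnected_branches(
    skel: SkeletonMap,
    step_budget: int = 30,
) -> SkeletonMap:
    """Bridge small disconnected skeleton components onto their neighbours.

    Every component except the largest is extended from both ends along
    a cubic fitted in its principal-axis frame, one pixel per step, and
    the first extension ray to touch another component is kept; bridged
    pixels take an inverse-distance-weighted convex combination of the
    radii at the two sides of the gap.  Components that reach nothing
    within ``step_budget`` steps are left untouched, so the number of
    connected components never increases.
    """
    skeleton = skel.skeleton.copy()
    radius = skel.radius.copy()
    labels, n = ndimage.label(skeleton, structure=np.ones((3, 3)))
    if n <= 1:
        return SkeletonMap(skeleton=skeleton, radius=radius,
                           pixel_class=skel.pixel_class.copy())
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    by_size = sorted(range(1, n + 1), key=lambda L: -sizes[L - 1])

    shape = skeleton.shape
    for lab in by_size[1:]:
        pts = np.argwhere(labels == lab).astype(float)
        if len(pts) < 2:
            continue
        ray_a, ray_b = _fit_and_extend(pts, step_budget)
        bridged = None
        for ray in (ray_a, ray_b):
            trail = []
            for point in ray:
                p = (int(round(point[0])), int(round(point[1])))
                if not (0 <= p[0] < shape[0] and 0 <= p[1] < shape[1]):
                    break
                if labels[p] != 0 and labels[p] != lab:
                    bridged = (trail, p, int(labels[p]))
                    break
                # contact also counts when an 8-neighbour belongs elsewhere
                nb = labels[max(0, p[0] - 1):p[0] + 2, max(0, p[1] - 1):p[1] + 2]
                other = nb[(nb != 0) & (nb != lab)]
                if other.size:
                    trail.append(p)
                    bridged = (trail, p, int(other[0]))
                    break
                trail.append(p)
            if bridged:
                break
        if not bridged:
            continue
        trail, contact, other_lab = bridged
        # radii anchors: nearest own pixel and the contact component pixel
        own = pts[np.argmin(np.abs(pts - np.array(trail[0] if trail else contact)).max(axis=1))]
        r1 = radius[int(own[0]), int(own[1])]
        r2 = radius[contact]
        if r1 == 0:
            r1 = r2
        if r2 == 0:
            r2 = r1
        a = np.array(own, dtype=float)
        b = np.array(contact, dtype=float)
        for p in trail:
            if skeleton[p]:
                continue
            d1 = max(np.linalg.norm(np.array(p) - a), 1e-9)
            d2 = max(np.linalg.norm(np.array(p) - b), 1e-9)
            w1 = (1 / d1) / (1 / d1 + 1 / d2)
            skeleton[p] = True
            radius[p] = w1 * r1 + (1 - w1) * r2
            labels[p] = lab
        # merge labels so later components can attach to the union
        labels[labels == lab] = other_lab

    from .skeletonize import _neighbor_counts  # reclassify after edits
    from .core import PixelClass

    counts = _neighbor_counts(skeleton)
    pixel_class = np.zeros(shape, dtype=np.uint8)
    pixel_class[skeleton & (counts <= 1)] = PixelClass.TERMINAL.value
    pixel_class[skeleton & (counts == 2)] = PixelClass.BODY.value
    pixel_class[skeleton & (counts >= 3)] = PixelClass.BRANCHING.value
    return SkeletonMap(skeleton=skeleton, radius=radius, pixel_class=pixel_class)
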