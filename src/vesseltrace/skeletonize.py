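"""From a binary vessel mask to a classified skeleton and its segments.

The mask is thinned to a one-pixel skeleton; each skeleton pixel keeps
the Euclidean distance to the nearest background pixel as its vessel
radius and is classified by its 8-neighbour count on the skeleton:
1 neighbour → terminal, 2 → body, ≥3 → branching.  Maximal chains of
body pixels bounded by terminal/branching pixels become *segments*,
the node unit of the downstream graph.  Terminal points inside the
optic-disk region are *roots* and seed the tree labels.

Thick blobs of mutually adjacent branching pixels are merged into a
single junction placed at their centroid; every junction records the
segments incident to it.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import morphology

from .core import (
    EmptySkeletonError,
    EndType,
    Junction,
    NoRootsError,
    PixelClass,
    Segment,
    SegmentSet,
    SkeletonMap,
    validate_mask,
)
from .orientation import WeightParams, angle_between_segments, segment_orientations

__all__ = [
    "skeletonize_mask",
    "extract_segments",
    "detect_optic_disk",
    "remove_spurious_segments",
]

_NEIGH_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)

# 8-neighbour offsets in scan order
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NEIGH_KERNEL, mode="constant")


def skeletonize_mask(mask: np.ndarray, method: str = "thin") -> SkeletonMap:
    """Thin a binary mask to a classified one-pixel skeleton.

    ``method='thin'`` uses Zhang–Suen thinning (clean junctions, fewer
    spurs); ``method='medial_axis'`` uses the medial-axis transform.
    Either way the per-pixel radius is the Euclidean distance transform
    of the mask evaluated on the skeleton.
    """
    grid = validate_mask(mask)
    if not grid.any():
        raise EmptySkeletonError("mask contains no vessel pixels")

    if method == "medial_axis":
        skel = morphology.medial_axis(grid)
    elif method == "thin":
        skel = morphology.skeletonize(grid)
    else:
        raise ValueError(f"unknown skeletonization method {method!r}")
    if not skel.any():  # pragma: no cover - thinning never empties a nonempty mask
        raise EmptySkeletonError("skeletonization produced an empty skeleton")

    dist = ndimage.distance_transform_edt(grid)
    radius = np.where(skel, dist, 0.0)

    counts = _neighbor_counts(skel)
    pixel_class = np.zeros(grid.shape, dtype=np.uint8)
    on = skel
    pixel_class[on & (counts <= 1)] = PixelClass.TERMINAL.value
    pixel_class[on & (counts == 2)] = PixelClass.BODY.value
    pixel_class[on & (counts >= 3)] = PixelClass.BRANCHING.value
    return SkeletonMap(skeleton=skel, radius=radius, pixel_class=pixel_class)


def _order_chain(pixels: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Order the pixels of a path (or cycle) chain by walking it."""
    if len(pixels) <= 1:
        return list(pixels)
    pset = set(pixels)
    nbrs = {
        p: [q for dr, dc in _OFFSETS if (q := (p[0] + dr, p[1] + dc)) in pset]
        for p in pixels
    }
    endpoints = sorted(p for p, ns in nbrs.items() if len(ns) <= 1)
    start = endpoints[0] if endpoints else min(pixels)  # cycle: break at scan-min
    chain = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [q for q in nbrs[cur] if q not in seen]
        if not nxt:
            break
        cur = min(nxt)
        chain.append(cur)
        seen.add(cur)
    return chain


def extract_segments(
    skel: SkeletonMap,
    disk: np.ndarray | None = None,
    require_roots: bool = True,
) -> SegmentSet:
    """Cut a classified skeleton into segments and junctions.

    ``disk`` is the optic-disk region (boolean raster): terminal points
    inside it become ROOT ends and their segments root segments.  With
    ``require_roots=False`` a rootless skeleton is allowed (useful for
    ordering isolated trees).
    """
    cls = skel.pixel_class
    branching = cls == PixelClass.BRANCHING.value

    # junctions: 8-connected clusters of branching pixels
    jlabels, njunc = ndimage.label(branching, structure=np.ones((3, 3)))
    junctions: list[Junction] = []
    order = []
    for lab in range(1, njunc + 1):
        pix = [tuple(p) for p in np.argwhere(jlabels == lab)]
        pt = tuple(np.mean(pix, axis=0))
        junctions.append(Junction(point=pt, pixels=sorted(pix)))
        order.append(min(pix))
    # deterministic junction numbering by scan order of their first pixel
    perm = sorted(range(njunc), key=lambda i: order[i])
    junctions = [junctions[i] for i in perm]
    jindex = np.full(skel.shape, -1, dtype=int)
    for idx, j in enumerate(junctions):
        for p in j.pixels:
            jindex[p] = idx

    # chains: skeleton minus branching pixels
    chains_mask = skel.skeleton & ~branching
    clabels, nchain = ndimage.label(chains_mask, structure=np.ones((3, 3)))

    disk_bool = None
    if disk is not None:
        disk_bool = np.asarray(disk) > 0

    raw_segments = []
    for lab in range(1, nchain + 1):
        pix = [tuple(p) for p in np.argwhere(clabels == lab)]
        chain = _order_chain(pix)

        def _adjacent_junctions(p):
            found = set()
            for dr, dc in _OFFSETS:
                q = (p[0] + dr, p[1] + dc)
                if 0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1]:
                    if jindex[q] >= 0:
                        found.add(int(jindex[q]))
            return sorted(found)

        j_first = _adjacent_junctions(chain[0])
        j_last = _adjacent_junctions(chain[-1])
        if len(chain) == 1:
            if len(j_first) >= 2:   # single pixel bridging two junctions
                jf, jl = j_first[0], j_first[1]
            elif j_first:           # one junction end, one terminal end
                jf, jl = j_first[0], None
            else:                   # isolated pixel
                jf = jl = None
        else:
            jf = j_first[0] if j_first else None
            jl = j_last[0] if j_last else None

        def _end_type(p, j):
            if j is not None:
                return EndType.BRANCH
            if disk_bool is not None and disk_bool[p]:
                return EndType.ROOT
            return EndType.END

        et = (_end_type(chain[0], jf), _end_type(chain[-1], jl))
        radii = [float(skel.radius[p]) for p in chain]
        raw_segments.append((chain, et, radii, (jf, jl)))

    # deterministic segment numbering by scan order of the first pixel
    raw_segments.sort(key=lambda t: t[0][0])
    segments: dict[int, Segment] = {}
    for sid, (chain, et, radii, jj) in enumerate(raw_segments):
        segments[sid] = Segment(id=sid, pixels=chain, end_types=et, radii=radii, junctions=jj)
        for j in set(x for x in jj if x is not None):
            junctions[j].members.append(sid)

    root_ids = {s.id for s in segments.values() if s.is_root}
    if require_roots and disk_bool is not None and not root_ids:
        raise NoRootsError("no terminal point falls inside the optic-disk region")

    return SegmentSet(
        segments=segments,
        junctions=junctions,
        root_ids=root_ids,
        disk_region=disk_bool,
        shape=skel.shape,
    )


def detect_optic_disk(
    image: np.ndarray,
    sigma: float = 10.0,
    percentile: float = 99.5,
    dilate: int = 5,
) -> np.ndarray:
    """Locate the optic disk as the brightest smoothed blob.

    The image is Gaussian-smoothed (``sigma`` px), thresholded strictly
    above its ``percentile`` intensity, and the largest connected
    component is kept and dilated by ``dilate`` px.  Raises when no
    pixel exceeds the threshold (e.g. a uniform image) — supply an
    explicit disk mask in that case.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    smooth = ndimage.gaussian_filter(img, sigma)
    thr = np.percentile(smooth, percentile)
    above = smooth > thr
    if not above.any():
        raise ValueError(
            "no bright blob found above the intensity threshold; "
            "please supply an optic-disk mask explicitly"
        )
    labels, n = ndimage.label(above)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = 1 + int(np.argmax(sizes))
    blob = labels == largest
    if dilate > 0:
        blob = morphology.dilation(blob, morphology.disk(dilate))
    return blob


def _spur_angle(segset: SegmentSet, orientations, seg: Segment) -> float:
    """Mean flanking angle β of a candidate spur.

    At each of the spur's two junctions, take the smallest undirected
    line angle between the spur's end direction and any continuing
    branch there; β averages the two junction values.
    """
    vals = []
    for which, jidx in zip(("first", "last"), seg.junctions):
        if jidx is None:
            continue
        mine = orientations[(seg.id, which)]
        best = None
        for other_id in segset.junctions[jidx].members:
            if other_id == seg.id:
                continue
            other = segset.segments[other_id]
            o_end = other.junction_end(jidx)
            theta = angle_between_segments(mine, orientations[(other_id, o_end)])
            line_angle = min(theta, 180.0 - theta)
            best = line_angle if best is None else min(best, line_angle)
        if best is not None:
            vals.append(best)
    return float(np.mean(vals)) if vals else 180.0


def remove_spurious_segments(
    segset: SegmentSet,
    beta_critical: float = 70.0,
    c_critical: int = 10,
    image: np.ndarray | None = None,
    params: WeightParams | None = None,
) -> SegmentSet:
    """Delete tiny low-angle connector segments between junctions.

    Skeletonization of a crossover often splits one 4-way junction into
    two 3-way junctions linked by a short spurious connector.  A segment
    with both ends branching, length ≤ ``c_critical`` and mean flanking
    angle β ≤ ``beta_critical`` is removed and its two junctions merged
    back into one, restoring the original 4-clique.  Iterates to a fixed
    point, so reapplication is a no-op.
    """
    params = params or WeightParams()
    current = segset
    while True:
        orientations = segment_orientations(current, image=image, params=params)
        removed: list[int] = []
        touched: set[int] = set()
        for seg in current:
            jf, jl = seg.junctions
            if jf is None or jl is None or jf == jl:
                continue
            if seg.length > c_critical:
                continue
            # only collapse a connector between two 3-way junctions back
            # into a 4-way one; larger junctions are left alone
            if len(current.junctions[jf].members) != 3:
                continue
            if len(current.junctions[jl].members) != 3:
                continue
            if jf in touched or jl in touched:
                continue  # one merge per junction per pass
            if _spur_angle(current, orientations, seg) <= beta_critical:
                removed.append(seg.id)
                touched.update((jf, jl))
        if not removed:
            return current
        current = _drop_and_merge(current, removed)


def _drop_and_merge(segset: SegmentSet, removed: list[int]) -> SegmentSet:
    """Remove segments and merge their junction pairs (union-find)."""
    parent = list(range(len(segset.junctions)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for sid in removed:
        a, b = segset.segments[sid].junctions
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    groups: dict[int, list[int]] = {}
    for i in range(len(segset.junctions)):
        groups.setdefault(find(i), []).append(i)

    new_junctions: list[Junction] = []
    remap: dict[int, int] = {}
    removed_set = set(removed)
    for root in sorted(groups):
        idxs = groups[root]
        pixels = sorted(p for i in idxs for p in segset.junctions[i].pixels)
        members = sorted(
            {m for i in idxs for m in segset.junctions[i].members} - removed_set
        )
        pt = tuple(np.mean(pixels, axis=0)) if pixels else segset.junctions[root].point
        for i in idxs:
            remap[i] = len(new_junctions)
        new_junctions.append(Junction(point=pt, pixels=pixels, members=members))

    new_segments: dict[int, Segment] = {}
    for seg in segset:
        if seg.id in removed_set:
            continue
        jf, jl = seg.junctions
        new_segments[seg.id] = Segment(
            id=seg.id,
            pixels=seg.pixels,
            end_types=seg.end_types,
            radii=seg.radii,
            junctions=(remap[jf] if jf is not None else None,
                       remap[jl] if jl is not None else None),
        )
    # prune junctions that lost all members
    keep = [i for i, j in enumerate(new_junctions) if j.members]
    final_remap = {old: new for new, old in enumerate(keep)}
    final_junctions = [new_junctions[i] for i in keep]
    for seg in new_segments.values():
        jf, jl = seg.junctions
        seg.junctions = (
            final_remap.get(jf) if jf is not None else None,
            final_remap.get(jl) if jl is not None else None,
        )
    return SegmentSet(
        segments=new_segments,
        junctions=final_junctions,
        root_ids=set(segset.root_ids) - removed_set,
        disk_region=segset.disk_region,
        shape=segset.shape,
    )
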