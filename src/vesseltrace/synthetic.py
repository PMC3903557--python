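"""Procedural generation of ground-truthed synthetic vascular scenes.

A scene emulates a fundus-image vessel network: a central optic disk
from which a configurable number of vessel trees radiate, each tree a
recursive binary branching structure whose *complexity* is measured by
the Shreve order of its root segment — which, for a proper tree, equals
its leaf count.  Complexity classes are LOW (root order 2–5), MEDIUM
(5–10) and HIGH (>10).  Adjacent tree axes are separated by the spread
angle γ (counter-clockwise); small γ packs the trees together and
produces inter-tree crossovers, the difficulty the tracer must resolve.

Trees are grown by a seeded stochastic grammar (branch lengths, branch
angles and curvature jitter drawn from configurable ranges), rendered
at a given stroke width, and every vessel pixel keeps its ground-truth
tree identity (crossing pixels keep all identities via per-tree masks).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from skimage import draw, morphology

from .core import EndType, Junction, Segment, SegmentSet

__all__ = [
    "Complexity",
    "LEAF_RANGES",
    "TreeSpec",
    "SceneSpec",
    "Branch",
    "TreePolylines",
    "SyntheticScene",
    "generate_tree",
    "compose_scene",
    "tree_segment_set",
    "benchmark_scene_specs",
    "generate_benchmark_datasets",
]

log = logging.getLogger(__name__)


class Complexity(Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


# admissible classic Shreve root orders (= leaf counts) per class
LEAF_RANGES: dict[Complexity, tuple[int, int]] = {
    Complexity.LOW: (2, 5),
    Complexity.MEDIUM: (5, 10),
    Complexity.HIGH: (11, 16),
}


@dataclass
class TreeSpec:
    """Growth parameters of one synthetic tree."""

    complexity: Complexity = Complexity.LOW
    axis_direction: float = 0.0            # degrees
    target_leaves: int | None = None       # drawn from the class range if None
    trunk_length: tuple[float, float] = (38.0, 52.0)
    branch_length: tuple[float, float] = (26.0, 42.0)
    branch_angle: tuple[float, float] = (18.0, 38.0)   # deviation per child, deg
    shrink: float = 0.85                    # length decay per generation
    min_length: float = 12.0
    jitter: float = 2.0                     # heading noise per step, deg
    step: float = 3.0                       # polyline sampling step, px


@dataclass
class SceneSpec:
    """Composition parameters of one synthetic scene."""

    n_trees: int = 8
    spread_angle_gamma: float = 30.0
    tree_specs: list[TreeSpec] = field(default_factory=list)
    image_size: tuple[int, int] = (512, 512)
    disk_radius: int = 40
    stroke_width: int = 3

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.spread_angle_gamma <= 360:
            raise ValueError("spread angle must lie in (0, 360] degrees")


@dataclass
class Branch:
    points: np.ndarray            # (m, 2) float, (row, col)
    parent: int | None
    depth: int
    leaves: int                   # leaf count of the subtree it feeds


@dataclass
class TreePolylines:
    branches: list[Branch]
    leaf_count: int
    axis_direction: float


@dataclass
class SyntheticScene:
    mask: np.ndarray              # bool
    disk: np.ndarray              # bool
    truth_labels: np.ndarray      # int32, 0 background, 1..n_trees (first tree wins)
    tree_masks: list[np.ndarray]  # per-tree bool rasters (authoritative truth)
    trees: list[TreePolylines]
    spec: SceneSpec


def _dir(deg: float) -> np.ndarray:
    r = math.radians(deg)
    return np.array([math.sin(r), math.cos(r)])


def _polyline(
    start: np.ndarray,
    heading: float,
    length: float,
    spec: TreeSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """A mildly curved polyline: heading jitter with mean reversion."""
    n_steps = max(2, int(round(length / spec.step)))
    pts = [np.asarray(start, float)]
    h = heading
    for _ in range(n_steps):
        h += rng.normal(0.0, spec.jitter) - 0.25 * (h - heading)
        pts.append(pts[-1] + spec.step * _dir(h))
    return np.array(pts)


def generate_tree(spec: TreeSpec, rng: np.random.Generator) -> TreePolylines:
    """Grow one tree by recursive binary branching.

    The leaf count is drawn from the complexity class's admissible
    range, so the classic Shreve order of the realized root segment
    falls in that range by construction.  Children deviate from the
    parent heading by angles drawn from ``branch_angle`` (one to each
    side); lengths decay by ``shrink`` per generation.
    """
    lo, hi = LEAF_RANGES[spec.complexity]
    n_leaves = spec.target_leaves if spec.target_leaves is not None else int(
        rng.integers(lo, hi + 1)
    )
    if n_leaves < 1:
        raise ValueError("a tree needs at least one leaf")

    branches: list[Branch] = []

    def grow(start: np.ndarray, heading: float, leaves: int, depth: int,
             parent: int | None) -> None:
        if depth == 0:
            length = rng.uniform(*spec.trunk_length)
        else:
            base = rng.uniform(*spec.branch_length)
            length = max(spec.min_length, base * spec.shrink ** (depth - 1))
        pts = _polyline(start, heading, length, spec, rng)
        idx = len(branches)
        branches.append(Branch(points=pts, parent=parent, depth=depth, leaves=leaves))
        if leaves == 1:
            return
        lo_split = max(1, int(math.ceil(leaves * 0.3)))
        hi_split = min(leaves - 1, int(math.floor(leaves * 0.7)))
        split = int(rng.integers(lo_split, hi_split + 1)) if hi_split > lo_split else lo_split
        a1 = rng.uniform(*spec.branch_angle)
        a2 = rng.uniform(*spec.branch_angle)
        end = pts[-1]
        grow(end, heading + a1, split, depth + 1, idx)
        grow(end, heading - a2, leaves - split, depth + 1, idx)

    grow(np.zeros(2), spec.axis_direction, n_leaves, 0, None)
    return TreePolylines(branches=branches, leaf_count=n_leaves,
                         axis_direction=spec.axis_direction)


def _raster_points(pts: np.ndarray, shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Rasterize a polyline into a deduplicated 8-connected pixel chain."""
    out: list[tuple[int, int]] = []
    ip = np.rint(pts).astype(int)
    for (r0, c0), (r1, c1) in zip(ip[:-1], ip[1:]):
        rr, cc = draw.line(r0, c0, r1, c1)
        for r, c in zip(rr, cc):
            if 0 <= r < shape[0] and 0 <= c < shape[1]:
                p = (int(r), int(c))
                if not out or out[-1] != p:
                    out.append(p)
    # drop immediate backtracks from rounding
    dedup: list[tuple[int, int]] = []
    for p in out:
        if len(dedup) >= 2 and dedup[-2] == p:
            dedup.pop()
        elif p not in dedup[-2:]:
            dedup.append(p)
    return dedup


def compose_scene(spec: SceneSpec, rng: np.random.Generator) -> SyntheticScene:
    """Place trees around the central disk and render the scene.

    Tree axes advance counter-clockwise by γ between neighbours; when
    ``n_trees * γ`` exceeds the full circle the separation wraps to
    ``360 / n_trees``.  Trunks start just inside the disk boundary so
    every tree owns exactly one root point.  Trees whose extent would
    leave the canvas are scaled down with a warning.
    """
    h, w = spec.image_size
    center = np.array([h / 2.0, w / 2.0])
    gamma = spec.spread_angle_gamma
    if spec.n_trees * gamma > 360.0:
        gamma = 360.0 / spec.n_trees
    base = float(rng.uniform(0.0, 360.0))

    tree_specs = list(spec.tree_specs)
    if len(tree_specs) < spec.n_trees:
        tree_specs = tree_specs + [TreeSpec()] * (spec.n_trees - len(tree_specs))

    trees: list[TreePolylines] = []
    tree_masks: list[np.ndarray] = []
    limit = min(h, w) / 2.0 - 4.0
    for t in range(spec.n_trees):
        axis = (base + t * gamma) % 360.0
        ts = replace(tree_specs[t], axis_direction=axis)
        tree = generate_tree(ts, rng)
        # alternate entry depths so root tips stay distinct even when
        # trees are packed at small angular separations
        start_radius = spec.disk_radius - (4.0 + 8.0 * (t % 2))
        start = center + max(start_radius, 2.0) * _dir(axis)
        pts_all = []
        for br in tree.branches:
            br.points = br.points + start
            pts_all.append(br.points)
        extent = max(float(np.max(np.linalg.norm(p - center, axis=1))) for p in pts_all)
        if extent > limit:
            scale = limit / extent
            log.warning("tree %d exceeds canvas (extent %.0f px); rescaling by %.2f",
                        t, extent, scale)
            for br in tree.branches:
                br.points = center + (br.points - center) * scale
        trees.append(tree)

        tmask = np.zeros((h, w), dtype=bool)
        for br in tree.branches:
            for p in _raster_points(br.points, (h, w)):
                tmask[p] = True
        if spec.stroke_width > 1:
            tmask = morphology.dilation(
                tmask, morphology.disk(spec.stroke_width // 2)
            )
        tree_masks.append(tmask)

    mask = np.zeros((h, w), dtype=bool)
    truth = np.zeros((h, w), dtype=np.int32)
    for t, tmask in enumerate(tree_masks):
        mask |= tmask
        truth[tmask & (truth == 0)] = t + 1

    rr, cc = draw.disk((center[0], center[1]), spec.disk_radius, shape=(h, w))
    disk = np.zeros((h, w), dtype=bool)
    disk[rr, cc] = True

    return SyntheticScene(mask=mask, disk=disk, truth_labels=truth,
                          tree_masks=tree_masks, trees=trees, spec=spec)


def tree_segment_set(tree: TreePolylines) -> SegmentSet:
    """Abstract segment set of one tree, straight from its polylines.

    Bypasses rendering and skeletonization: each branch becomes one
    segment, each bifurcation one 3-way junction.  The trunk's proximal
    end is marked ROOT, leaf tips END.  Useful as a topology oracle —
    the classic Shreve order of the root segment is exactly the
    generator's leaf count.
    """
    shape = None
    segments: dict[int, Segment] = {}
    junctions: list[Junction] = []
    junction_of_branch_end: dict[int, int] = {}

    children: dict[int, list[int]] = {}
    for idx, br in enumerate(tree.branches):
        if br.parent is not None:
            children.setdefault(br.parent, []).append(idx)

    mins = np.min([br.points.min(axis=0) for br in tree.branches], axis=0)
    offset = np.maximum(0, -mins) + 2

    for idx, br in enumerate(tree.branches):
        if idx in children:
            pt = tuple((br.points[-1] + offset))
            junction_of_branch_end[idx] = len(junctions)
            junctions.append(Junction(point=pt, pixels=[tuple(np.rint(pt).astype(int))]))

    big = 1 << 30
    for idx, br in enumerate(tree.branches):
        pts = br.points + offset
        chain = _raster_points(pts, (big, big))
        if len(chain) < 2:
            chain = [tuple(np.rint(pts[0]).astype(int)), tuple(np.rint(pts[-1]).astype(int))]
        jf = junction_of_branch_end.get(br.parent) if br.parent is not None else None
        jl = junction_of_branch_end.get(idx)
        et_first = EndType.BRANCH if jf is not None else EndType.ROOT
        et_last = EndType.BRANCH if jl is not None else EndType.END
        segments[idx] = Segment(
            id=idx, pixels=chain, end_types=(et_first, et_last),
            radii=[1.0] * len(chain), junctions=(jf, jl),
        )
        for j in {x for x in (jf, jl) if x is not None}:
            junctions[j].members.append(idx)

    return SegmentSet(segments=segments, junctions=junctions,
                      root_ids={0}, disk_region=None, shape=shape)


# ---------------------------------------------------------------------------
# benchmark datasets

_DATASET1_SUBSETS = [
    ["low"] * 8,
    ["low"] * 4 + ["medium"] * 4,
    ["medium"] * 8,
    ["medium"] * 4 + ["high"] * 4,
    ["high"] * 8,
]
_DATASET2_TREE_COUNTS = [3, 5, 7, 9, 11, 12]
_DATASET3_GAMMAS = [360.0, 300.0, 240.0, 180.0, 120.0, 60.0]


def _mixed_complexities(n: int) -> list[str]:
    """Round-robin 1/3 per complexity class."""
    cycle = ["low", "medium", "high"]
    return [cycle[i % 3] for i in range(n)]


def benchmark_scene_specs(
    which: int,
    image_size: tuple[int, int] = (512, 512),
    disk_radius: int = 40,
    stroke_width: int = 3,
) -> list[tuple[str, SceneSpec]]:
    """Scene specs of one benchmark dataset, one entry per subset.

    Dataset 1 varies the complexity mix (8 trees, γ=30°); dataset 2 the
    tree count ({3,5,7,9,11,12}, mixed complexity, γ=30°); dataset 3
    the spread angle ({360°,…,60°}, 8 trees, mixed complexity).
    """
    out: list[tuple[str, SceneSpec]] = []
    if which == 1:
        for si, mix in enumerate(_DATASET1_SUBSETS):
            specs = [TreeSpec(complexity=Complexity(c)) for c in mix]
            out.append((f"d1_s{si + 1}", SceneSpec(
                n_trees=8, spread_angle_gamma=30.0, tree_specs=specs,
                image_size=image_size, disk_radius=disk_radius,
                stroke_width=stroke_width)))
    elif which == 2:
        for n in _DATASET2_TREE_COUNTS:
            specs = [TreeSpec(complexity=Complexity(c)) for c in _mixed_complexities(n)]
            out.append((f"d2_n{n}", SceneSpec(
                n_trees=n, spread_angle_gamma=30.0, tree_specs=specs,
                image_size=image_size, disk_radius=disk_radius,
                stroke_width=stroke_width)))
    elif which == 3:
        # here γ is the *total* angular coverage of the 8 trees (the only
        # reading under which all six values are geometrically realizable
        # and crossovers grow as γ shrinks); adjacent separation is γ/8
        for g in _DATASET3_GAMMAS:
            specs = [TreeSpec(complexity=Complexity(c)) for c in _mixed_complexities(8)]
            out.append((f"d3_g{int(g)}", SceneSpec(
                n_trees=8, spread_angle_gamma=g / 8.0, tree_specs=specs,
                image_size=image_size, disk_radius=disk_radius,
                stroke_width=stroke_width)))
    else:
        raise ValueError("which must be 1, 2 or 3")
    return out


def generate_benchmark_datasets(
    which: int,
    n_per_subset: int,
    seed: int,
    out_dir: str | Path,
    image_size: tuple[int, int] = (512, 512),
) -> Path:
    """Render one benchmark dataset to disk with a manifest TSV.

    Per image: mask PNG, disk PNG, 16-bit truth-label PNG and a
    polylines JSON.  Returns the dataset directory.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for subset, spec in benchmark_scene_specs(which, image_size=image_size):
        for i in range(n_per_subset):
            scene = compose_scene(spec, rng)
            stem = f"{subset}_{i:03d}"
            Image.fromarray((scene.mask * 255).astype(np.uint8)).save(
                out_dir / f"{stem}_mask.png")
            Image.fromarray((scene.disk * 255).astype(np.uint8)).save(
                out_dir / f"{stem}_disk.png")
            Image.fromarray(scene.truth_labels.astype(np.uint16)).save(
                out_dir / f"{stem}_truth.png")
            poly = [
                {
                    "leaf_count": t.leaf_count,
                    "axis_direction": t.axis_direction,
                    "branches": [
                        {"parent": b.parent, "depth": b.depth,
                         "points": np.round(b.points, 2).tolist()}
                        for b in t.branches
                    ],
                }
                for t in scene.trees
            ]
            (out_dir / f"{stem}_trees.json").write_text(json.dumps(poly))
            rows.append({
                "image": stem, "subset": subset, "n_trees": spec.n_trees,
                "gamma": spec.spread_angle_gamma,
                "complexities": ",".join(ts.complexity.value for ts in spec.tree_specs),
                "seed": seed,
            })
    import pandas as pd

    pd.DataFrame(rows).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return out_dir
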