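"""File formats: masks, tables, graphs, weight matrices, overlays, SWC.

Masks and disk regions travel as single-channel 0/255 PNG/TIFF; radius
maps as 32-bit TIFF; tabular products (segments, ordering, edge
weights, labels) as TSV; the affinity matrix as Matrix Market; traced
trees as standard 7-column SWC so external morphology tools (including
DIADEM-style scorers) can consume them.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from PIL import Image
from scipy import io as sio
from scipy import sparse

from .core import SegmentSet
from .graph import VesselGraph
from .ordering import OrderingMap
from .propagate import TreeLabeling, UNASSIGNED
from .weights import WeightMatrix

__all__ = [
    "read_mask",
    "write_mask",
    "write_radius_map",
    "segments_to_tsv",
    "graph_to_tsv",
    "graph_to_graphml",
    "ordering_to_tsv",
    "weights_to_mtx",
    "weights_to_tsv",
    "labels_to_tsv",
    "write_overlay",
    "tree_to_swc",
]


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 127


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)


def write_radius_map(radius: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(radius, dtype=np.float32)).save(path, format="TIFF")


def _runlength(pixels) -> str:
    return ";".join(f"{r},{c}" for r, c in pixels)


def segments_to_tsv(segset: SegmentSet, path: str | Path) -> None:
    rows = [
        {
            "segment_id": s.id,
            "end1_type": s.end_types[0].value,
            "end2_type": s.end_types[1].value,
            "length": s.length,
            "mean_radius": float(np.mean(s.radii)),
            "pixels": _runlength(s.pixels),
        }
        for s in segset
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def graph_to_tsv(vg: VesselGraph, edge_path: str | Path, junction_path: str | Path,
                 simplified: bool = False) -> None:
    edges = [
        {"i": a, "j": b, "junctions": ",".join(map(str, d.get("junctions", []))),
         "simplified": simplified}
        for a, b, d in vg.graph.edges(data=True)
    ]
    pd.DataFrame(edges).to_csv(edge_path, sep="\t", index=False)
    juncs = [
        {"junction": c.junction_index, "row": c.point[0], "col": c.point[1],
         "size": c.size, "members": ",".join(map(str, c.members))}
        for c in vg.cliques
    ]
    pd.DataFrame(juncs).to_csv(junction_path, sep="\t", index=False)


def graph_to_graphml(vg: VesselGraph, path: str | Path) -> None:
    g = nx.Graph()
    g.add_nodes_from(vg.graph.nodes)
    for a, b, d in vg.graph.edges(data=True):
        g.add_edge(a, b, junctions=",".join(map(str, d.get("junctions", []))))
    nx.write_graphml(g, path)


def ordering_to_tsv(om: OrderingMap, path: str | Path) -> None:
    rows = [
        {"segment_id": sid, "mu": om.order[sid], "rule_tag": om.provenance.get(sid, "")}
        for sid in sorted(om.order)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def weights_to_mtx(wm: WeightMatrix, path: str | Path) -> None:
    sio.mmwrite(str(path), sparse.csr_matrix(wm.W))


def weights_to_tsv(wm: WeightMatrix, path: str | Path) -> None:
    pd.DataFrame(wm.edge_records).to_csv(path, sep="\t", index=False)


def labels_to_tsv(labeling: TreeLabeling, path: str | Path) -> None:
    rows = [
        {"segment_id": sid, "tree_id": lab, "score": labeling.score.get(sid, 0.0)}
        for sid, lab in sorted(labeling.label.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_overlay(segset: SegmentSet, labeling: TreeLabeling, shape,
                  path: str | Path) -> None:
    """Colored PNG with one color per traced tree."""
    rng = np.random.default_rng(0)
    labels = sorted({v for v in labeling.label.values() if v != UNASSIGNED})
    palette = {lab: rng.integers(64, 255, size=3) for lab in labels}
    img = np.zeros((*shape, 3), dtype=np.uint8)
    for seg in segset:
        lab = labeling.label.get(seg.id, UNASSIGNED)
        color = palette.get(lab, np.array([128, 128, 128]))
        for r, c in seg.pixels:
            img[r, c] = color
    Image.fromarray(img).save(path)


def tree_to_swc(tree: nx.DiGraph, segset: SegmentSet, root_id: int,
                path: str | Path) -> None:
    """One traced tree as standard SWC (id, type, x, y, z, radius, parent).

    Each skeleton pixel becomes one SWC sample (type 2, generic
    dendrite-like fiber); x=col, y=row, z=0.  A child segment's chain
    is oriented away from its parent and attached to the parent's
    nearest sample.
    """
    lines = []
    next_id = 1
    seg_samples: dict[int, list[tuple[int, tuple[int, int]]]] = {}

    order = [root_id] + [v for _, v in nx.bfs_edges(tree, root_id)] if tree.nodes else [root_id]
    parent_of = {v: u for u, v in tree.edges}
    for sid in order:
        seg = segset.segments[sid]
        pixels = list(seg.pixels)
        parent_seg = parent_of.get(sid)
        parent_sample = -1
        if parent_seg is not None and parent_seg in seg_samples:
            # attach at the end nearest to the parent chain
            ppts = np.array([p for _, p in seg_samples[parent_seg]], dtype=float)

            def _mind(p):
                return float(np.min(np.linalg.norm(ppts - np.array(p, dtype=float), axis=1)))

            if _mind(pixels[-1]) < _mind(pixels[0]):
                pixels = pixels[::-1]
            d = [np.linalg.norm(ppts - np.array(pixels[0], dtype=float), axis=1)]
            parent_sample = seg_samples[parent_seg][int(np.argmin(d[0]))][0]
        radii = seg.radii if len(seg.radii) == len(seg.pixels) else [1.0] * len(pixels)
        if pixels is not seg.pixels and len(radii) == len(pixels):
            radii = radii[::-1]
        samples = []
        prev = parent_sample
        for p, r in zip(pixels, radii):
            lines.append(f"{next_id} 2 {p[1]} {p[0]} 0 {max(r, 0.5):.3f} {prev}")
            samples.append((next_id, p))
            prev = next_id
            next_id += 1
        seg_samples[sid] = samples

    Path(path).write_text("\n".join(lines) + "\n")
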