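"""Medial-axis extraction and ordering of the arch center-line.

The arch mask is thinned to a 1-px-wide skeleton by topology-preserving
iterative thinning.  Because thinning leaves short spurs at tooth cusps, the
skeleton is reduced to its main branch: the longest shortest path between any
two endpoints of the 8-neighbor pixel graph (the graph diameter restricted to
endpoints).  The result is an ordered open curve, oriented left to right in
image coordinates so the curve parameter origin is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from skimage.morphology import skeletonize

from .errors import InputError

__all__ = ["SkeletonCurve", "medial_axis", "prune_and_order"]

_NEIGHBORS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


@dataclass
class SkeletonCurve:
    """An ordered medial-axis polyline.

    ``points`` is an ``(N, 2)`` array of ``(x, y)`` pixel coordinates
    (x = column, y = row), consecutive points 8-adjacent, no repeats.
    """

    points: np.ndarray
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise InputError("skeleton curve needs >= 2 (x, y) points")

    def __len__(self) -> int:
        return len(self.points)


def medial_axis(mask: np.ndarray) -> np.ndarray:
    """Thin a connected binary mask to a 1-px skeleton (boolean image).

    Topology-preserving: a connected mask yields a connected skeleton that is
    a subset of the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("cannot skeletonize an empty mask")
    return skeletonize(mask)


def _pixel_graph(pixels: np.ndarray) -> nx.Graph:
    nodes = sorted(tuple(p) for p in pixels)  # sorted: deterministic BFS ties
    node_set = set(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for r, c in nodes:
        for dr, dc in _NEIGHBORS:
            nb = (r + dr, c + dc)
            if nb in node_set:
                g.add_edge((r, c), nb)
    return g


def prune_and_order(skeleton_pixels: np.ndarray) -> SkeletonCurve:
    """Extract the main branch of a skeleton image as an ordered curve.

    Builds the 8-neighbor graph of skeleton pixels, finds the longest
    shortest path between endpoint pixels (degree 1), discards all side
    branches, and orients the path from the end with the smaller x.
    """
    skeleton_pixels = np.asarray(skeleton_pixels, dtype=bool)
    coords = np.argwhere(skeleton_pixels)  # (row, col)
    if len(coords) < 2:
        raise InputError(f"skeleton has {len(coords)} pixels; need >= 2")
    g = _pixel_graph(coords)
    if not nx.is_connected(g):
        biggest = max(nx.connected_components(g), key=lambda c: (len(c), -min(c)[0]))
        g = g.subgraph(biggest).copy()
    endpoints = sorted(n for n in g if g.degree(n) == 1)
    if len(endpoints) >= 2:
        best = None
        for src in endpoints:
            lengths = nx.single_source_shortest_path_length(g, src)
            for dst in endpoints:
                if dst <= src:
                    continue
                d = lengths.get(dst)
                if d is not None and (best is None or d > best[0]):
                    best = (d, src, dst)
        _, src, dst = best
        path = nx.shortest_path(g, src, dst)
    else:
        # closed or blob-like skeleton: double-sweep pseudo-diameter
        start = min(g.nodes)
        far1 = max(nx.single_source_shortest_path_length(g, start).items(), key=lambda kv: (kv[1], kv[0]))[0]
        far2 = max(nx.single_source_shortest_path_length(g, far1).items(), key=lambda kv: (kv[1], kv[0]))[0]
        path = nx.shortest_path(g, far1, far2)
    pts = np.array([(c, r) for r, c in path], dtype=np.float64)  # (x, y)
    first, last = pts[0], pts[-1]
    if (first[0], first[1]) > (last[0], last[1]):
        pts = pts[::-1]
    return SkeletonCurve(points=pts, source_shape=tuple(skeleton_pixels.shape))
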