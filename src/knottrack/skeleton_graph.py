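"""Skeleton topology: branch points, contour ordering, filament graphs.

A skeleton with no branch pixels is ordered into a contour directly by
geodesic distance from a start endpoint.  A branched skeleton ("knot")
is mapped to a graph whose vertices are 8-connected groups of branch
pixels (Vb) or filament-segment pixels (Vf) and whose edges record the
Moore adjacency between groups; a segment that meets the same branch
group at both of its ends contributes two parallel edges (a loop, the
signature of a filament crossing itself).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .segmentation import Skeleton

__all__ = [
    "PixelContour",
    "FilamentGraph",
    "find_branch_pixels",
    "find_endpoints",
    "order_unbranched",
    "build_graph",
]

_MOORE = np.ones((3, 3), dtype=int)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
            (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class PixelContour:
    """Ordered (row, col) pixel sequence from the clamped start to the end.

    Consecutive points are Moore neighbors except at branch crossings,
    where small jumps (<= 2 px) can occur at vertex junctions.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=int).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        """(N, 2) float array in (x, y) = (col, row) order."""
        return self.points[:, ::-1].astype(float)


@dataclass
class FilamentGraph:
    """Graph of branch (Vb) and filament-segment (Vf) vertex groups.

    ``graph`` is an undirected :class:`networkx.MultiGraph`; node
    attributes are ``kind`` ('branch' | 'segment') and ``pixels`` (an
    (N, 2) array).  Edge attribute ``port`` is the segment-side pixel
    at which the segment meets the branch, used to orient traversals.
    Directionality is imposed at traversal time: paths leave
    ``start_vertex`` and terminate at ``end_vertex`` when one exists.
    """

    graph: nx.MultiGraph
    start_vertex: int
    end_vertex: int | None
    start_pixel: tuple[int, int]
    shape: tuple[int, int]

    def pixels_of(self, node: int) -> np.ndarray:
        return self.graph.nodes[node]["pixels"]

    def kind_of(self, node: int) -> str:
        return self.graph.nodes[node]["kind"]

    @property
    def segment_vertices(self) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "segment"]

    @property
    def branch_vertices(self) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "branch"]


# --------------------------------------------------------------------------
# branch / endpoint detection
# --------------------------------------------------------------------------

def _moore_sums(mask: np.ndarray) -> np.ndarray:
    return ndimage.convolve(mask.astype(int), _MOORE, mode="constant")


def find_branch_pixels(skeleton: Skeleton) -> set[tuple[int, int]]:
    """Lit pixels whose 3x3 Moore sum (center included) is >= 4.

    Since the center pixel is itself lit, this selects pixels with at
    least three lit neighbors — the junctions of a self-intersection.
    """
    counts = _moore_sums(skeleton.mask)
    return {tuple(p) for p in np.argwhere(skeleton.mask & (counts >= 4))}


def find_endpoints(skeleton: Skeleton) -> list[tuple[int, int]]:
    """Lit pixels with exactly one lit Moore neighbor (free filament tips)."""
    counts = _moore_sums(skeleton.mask)
    return [tuple(p) for p in np.argwhere(skeleton.mask & (counts == 2))]


# --------------------------------------------------------------------------
# geodesic ordering of unbranched skeletons
# --------------------------------------------------------------------------

def _pixel_graph(pixels: np.ndarray):
    """Sparse euclidean-weighted Moore adjacency over a pixel set."""
    index = {tuple(p): i for i, p in enumerate(map(tuple, pixels))}
    rows, cols, w = [], [], []
    for (r, c), i in index.items():
        for dr, dc in _OFFSETS:
            j = index.get((r + dr, c + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
                w.append(float(np.hypot(dr, dc)))
    n = len(pixels)
    return coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr(), index


def geodesic_distances(pixels: np.ndarray, source: tuple[int, int]) -> np.ndarray:
    """Geodesic (along-skeleton, euclidean-weighted) distance from source."""
    adj, index = _pixel_graph(pixels)
    return dijkstra(adj, directed=False, indices=index[tuple(source)])


def order_unbranched(skeleton: Skeleton, start: tuple[int, int]) -> PixelContour:
    """Order an unbranched skeleton's pixels by geodesic distance from start."""
    if find_branch_pixels(skeleton):
        raise ValueError("skeleton is branched; build a graph instead")
    start = tuple(int(v) for v in start)
    pixels = skeleton.pixels
    if skeleton.n_pixels == 1:
        return PixelContour(pixels)
    endpoints = {tuple(p) for p in skeleton.endpoints}
    if start not in endpoints:
        raise ValueError(f"start {start} is not a skeleton endpoint")
    dist = geodesic_distances(pixels, start)
    if not np.isfinite(dist).all():
        raise ValueError("skeleton is disconnected")
    return PixelContour(pixels[np.argsort(dist, kind="stable")])


# --------------------------------------------------------------------------
# graph construction for branched skeletons
# --------------------------------------------------------------------------

def _components(pixels: set[tuple[int, int]]) -> list[np.ndarray]:
    """8-connected components of a pixel set, in scan order."""
    if not pixels:
        return []
    arr = np.array(sorted(pixels))
    shape = (arr[:, 0].max() + 2, arr[:, 1].max() + 2)
    m = np.zeros(shape, dtype=bool)
    m[arr[:, 0], arr[:, 1]] = True
    lab, n = ndimage.label(m, structure=_MOORE)
    comps = []
    for k in range(1, n + 1):
        comps.append(np.argwhere(lab == k))
    comps.sort(key=lambda c: (c[:, 0].min(), c[:, 1].min(), len(c)))
    return comps


def _segment_ends(pixels: np.ndarray) -> list[tuple[int, int]]:
    """Intrinsic endpoints of a segment component (<=1 neighbor inside)."""
    pset = {tuple(p) for p in pixels}
    ends = []
    for p in map(tuple, pixels):
        n_nb = sum((p[0] + dr, p[1] + dc) in pset for dr, dc in _OFFSETS)
        if n_nb <= 1:
            ends.append(p)
    if not ends:  # cyclic segment; use scan-order first pixel as the port
        ends = [tuple(pixels[0])]
    return ends


def _consolidate_junctions(seg_pixels: set[tuple[int, int]],
                           branch_pixels: set[tuple[int, int]],
                           merge_len: int) -> tuple[set, set]:
    """Absorb short slivers between distinct branch groups into the junction.

    Skeletonizing a shallow X-crossing yields a "bowtie": two Y-points
    joined by a short segment that the filament really traverses twice.
    Segments of at most ``merge_len`` pixels touching two or more
    distinct branch groups are reclassified as branch pixels so the
    crossing becomes a single junction group.
    """
    while True:
        br_comps = _components(branch_pixels)
        bidx: dict[tuple[int, int], int] = {}
        for i, comp in enumerate(br_comps):
            bidx.update({tuple(p): i for p in comp})
        merged = False
        for comp in _components(seg_pixels):
            if len(comp) > merge_len:
                continue
            adjacent = set()
            for p in map(tuple, comp):
                for dr, dc in _OFFSETS:
                    j = bidx.get((p[0] + dr, p[1] + dc))
                    if j is not None:
                        adjacent.add(j)
            if len(adjacent) >= 2:
                sliver = {tuple(p) for p in comp}
                branch_pixels = branch_pixels | sliver
                seg_pixels = seg_pixels - sliver
                merged = True
                break
        if not merged:
            return seg_pixels, branch_pixels


def build_graph(skeleton: Skeleton,
                branch_pixels: set[tuple[int, int]] | None = None,
                start: tuple[int, int] | None = None,
                junction_merge_len: int = 14) -> FilamentGraph:
    """Map a branched skeleton to a branch/segment multigraph.

    Branch pixels (Moore-sum criterion) are grouped into Vb vertices,
    the remaining pixels into Vf vertices; an edge joins a Vf to a Vb
    for every end of the segment adjacent to that branch group, so a
    self-merging loop yields two parallel edges.  Short slivers between
    branch groups (skeletonization bowties at shallow crossings) are
    folded into a single junction group (``junction_merge_len``).
    ``start`` must lie on a terminal segment and fixes the traversal
    direction.
    """
    if branch_pixels is None:
        branch_pixels = find_branch_pixels(skeleton)
    if not branch_pixels:
        raise ValueError("skeleton has no branch pixels; use order_unbranched")
    if start is None:
        eps = find_endpoints(skeleton)
        if not eps:
            raise ValueError("no endpoints and no start supplied")
        start = eps[0]
    start = tuple(int(v) for v in start)
    if start in branch_pixels:
        raise ValueError("start pixel lies on a branch group")

    all_pixels = {tuple(p) for p in skeleton.pixels}
    if start not in all_pixels:
        raise ValueError("start pixel is not on the skeleton")
    seg_pixels = all_pixels - branch_pixels
    if junction_merge_len > 0:
        seg_pixels, branch_pixels = _consolidate_junctions(
            seg_pixels, set(branch_pixels), junction_merge_len)

    g = nx.MultiGraph()
    seg_comps = _components(seg_pixels)
    br_comps = _components(branch_pixels)
    # stable integer labels: segments first (1..k), then branches
    node_of_pixel: dict[tuple[int, int], int] = {}
    nid = 0
    for comp in seg_comps:
        nid += 1
        g.add_node(nid, kind="segment", pixels=comp)
        node_of_pixel.update({tuple(p): nid for p in comp})
    for comp in br_comps:
        nid += 1
        g.add_node(nid, kind="branch", pixels=comp)
        node_of_pixel.update({tuple(p): nid for p in comp})

    # edges: one per (segment end, adjacent branch group)
    for node in list(g.nodes):
        if g.nodes[node]["kind"] != "segment":
            continue
        comp = g.nodes[node]["pixels"]
        touched: set[int] = set()
        for end in _segment_ends(comp):
            seen_here: set[int] = set()
            for dr, dc in _OFFSETS:
                q = (end[0] + dr, end[1] + dc)
                other = node_of_pixel.get(q)
                if other is not None and other != node \
                        and g.nodes[other]["kind"] == "branch" \
                        and other not in seen_here:
                    g.add_edge(node, other, port=end)
                    seen_here.add(other)
                    touched.add(other)
        # defensive: segment flank touching a branch away from both ends
        for p in map(tuple, comp):
            for dr, dc in _OFFSETS:
                other = node_of_pixel.get((p[0] + dr, p[1] + dc))
                if other is not None and other != node \
                        and g.nodes[other]["kind"] == "branch" \
                        and other not in touched:
                    g.add_edge(node, other, port=p)
                    touched.add(other)

    start_vertex = node_of_pixel[start]
    if g.nodes[start_vertex]["kind"] != "segment":
        raise ValueError("start pixel must lie on a filament segment")
    endpoints = find_endpoints(skeleton)
    end_vertex = None
    best = -1.0
    for ep in endpoints:
        node = node_of_pixel.get(tuple(ep))
        if node is None or node == start_vertex:
            continue
        if g.nodes[node]["kind"] != "segment":
            continue
        d = float(np.hypot(ep[0] - start[0], ep[1] - start[1]))
        if d > best:
            best = d
            end_vertex = node
    return FilamentGraph(graph=g, start_vertex=start_vertex,
                         end_vertex=end_vertex, start_pixel=start,
                         shape=skeleton.shape)
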