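"""Knot resolution: pick the physical filament path through a crossing.

A branched skeleton admits many walks from the clamped start to the
free end.  Candidate paths are enumerated over the branch/segment
graph under the physical traversal rule — each filament segment (Vf)
is covered exactly once, branch groups (Vb) may be crossed repeatedly,
and each edge is used at most once per direction — with a beam cap on
the branching factor to avoid combinatorial blow-up.  Each candidate
is converted to an ordered contour and scored against the template
(the last successfully resolved contour) by dynamic time warping; the
minimum-score path wins.  The tracking loop propagates the template
and the start point frame to frame and accepts programmatic manual
overrides for frames the automatic search cannot resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import Skeleton
from .skeleton_graph import (FilamentGraph, PixelContour, build_graph,
                             find_branch_pixels, find_endpoints,
                             geodesic_distances, order_unbranched)

__all__ = [
    "GraphPath",
    "TemplateState",
    "ManualOverride",
    "TrackConfig",
    "Track",
    "UnresolvableFrameError",
    "select_key_vertices",
    "enumerate_paths",
    "path_to_contour",
    "dtw_score",
    "resolve_frame",
    "track_series",
]


class UnresolvableFrameError(RuntimeError):
    """No admissible path exists; manual override required."""


# half-width of the corridor around the entry->exit chord within which
# junction-group pixels are attributed to a given crossing traversal
_JUNCTION_CORRIDOR_PX = 1.5


@dataclass
class GraphPath:
    """An ordered walk through a :class:`FilamentGraph`.

    ``vertex_sequence`` starts at the graph's start vertex;
    ``edge_sequence`` holds the (u, v, key) multigraph edges traversed,
    one fewer than the vertices.
    """

    vertex_sequence: list[int]
    edge_sequence: list[tuple[int, int, int]]


@dataclass
class TemplateState:
    """The reference contour for path selection (last resolved frame)."""

    contour: PixelContour
    frame_index: int

    def __post_init__(self) -> None:
        if len(self.contour) == 0:
            raise ValueError("template contour must be non-empty")


@dataclass(frozen=True)
class ManualOverride:
    """User-supplied vertex-label path for one frame."""

    frame_index: int
    region_sequence: tuple[int, ...]


@dataclass(frozen=True)
class TrackConfig:
    """Tracking-loop parameters.

    ``path_cap`` is the beam width per frontier expansion during path
    enumeration; ``max_paths`` bounds the number of complete candidate
    paths scored per frame.  ``template_mode`` selects whether the
    template is the last resolved contour (default) or only the last
    unbranched one.
    """

    path_cap: int = 10
    max_paths: int = 100
    template_mode: str = "last_resolved"  # or "last_unbranched"
    start_xy: tuple[float, float] | None = None  # frame-1 seed, (x, y)

    def __post_init__(self) -> None:
        if self.template_mode not in ("last_resolved", "last_unbranched"):
            raise ValueError("template_mode must be last_resolved or last_unbranched")
        if self.path_cap < 1:
            raise ValueError("path_cap must be >= 1")


@dataclass
class Track:
    """Per-frame resolved contours plus bookkeeping.

    ``contours[k]`` is the resolved :class:`PixelContour` of frame k or
    None when the frame was skipped; ``skipped`` lists skipped frame
    indices; ``info`` holds per-frame diagnostics (branch count, number
    of candidate paths, selected DTW score).
    """

    contours: list[PixelContour | None]
    skipped: list[int] = field(default_factory=list)
    info: list[dict] = field(default_factory=list)

    @property
    def resolved_frames(self) -> list[int]:
        return [i for i, c in enumerate(self.contours) if c is not None]


# --------------------------------------------------------------------------
# key-vertex selection and path enumeration
# --------------------------------------------------------------------------

def _vertex_template_scores(graph: FilamentGraph,
                            template: TemplateState) -> dict[int, float]:
    from scipy.spatial import cKDTree

    tree = cKDTree(template.contour.points.astype(float))
    scores = {}
    for node in graph.graph.nodes:
        d, _ = tree.query(graph.pixels_of(node).astype(float))
        scores[node] = float(np.mean(d))
    return scores


def select_key_vertices(graph: FilamentGraph,
                        template: TemplateState) -> list[int]:
    """The three vertices nearest the template (all if fewer than 3).

    Each vertex is scored by the mean, over its pixels, of the nearest
    Euclidean distance to any template point; ties break by vertex
    label order.
    """
    scores = _vertex_template_scores(graph, template)
    ranked = sorted(scores, key=lambda n: (scores[n], n))
    return ranked[:3]


def enumerate_paths(graph: FilamentGraph,
                    key_vertices: list[int] | None = None,
                    cap: int = 10,
                    max_paths: int = 100,
                    template: TemplateState | None = None) -> list[GraphPath]:
    """Enumerate candidate start-to-end walks, beam-capped per expansion.

    Traversal rule: a segment vertex may be visited once, a branch
    vertex any number of times, an edge at most once per direction.  A
    walk is complete when it reaches the end vertex having covered
    every segment vertex; if the graph has no end vertex the walk
    terminates once all segments are visited.  If no full-coverage walk
    exists, walks that merely reach the end vertex are accepted as a
    fallback.  Expansion order is template-greedy: children among the
    key vertices (nearest the template) are tried first.
    """
    g = graph.graph
    segs = set(graph.segment_vertices)
    key_set = set(key_vertices or [])
    tscores = (_vertex_template_scores(graph, template)
               if template is not None else {n: 0.0 for n in g.nodes})

    def child_priority(v: int) -> tuple:
        return (v not in key_set, tscores.get(v, 0.0), v)

    max_depth = 2 * g.number_of_edges() + 1
    results: list[GraphPath] = []
    fallback: list[GraphPath] = []

    def dfs(node: int, visited: frozenset, used: frozenset,
            vseq: list[int], eseq: list[tuple[int, int, int]]) -> None:
        if len(results) >= max_paths or len(vseq) > max_depth:
            return
        if node == graph.end_vertex and len(vseq) > 1:
            if segs <= visited:
                results.append(GraphPath(list(vseq), list(eseq)))
            elif len(fallback) < max_paths:
                fallback.append(GraphPath(list(vseq), list(eseq)))
            return
        if graph.end_vertex is None and segs <= visited:
            results.append(GraphPath(list(vseq), list(eseq)))
            return
        children = []
        for _, v, key in g.edges(node, keys=True):
            if (node, v, key) in used:
                continue
            if v in segs and v in visited:
                continue
            children.append((v, key))
        children.sort(key=lambda vk: (child_priority(vk[0]), vk[1]))
        for v, key in children[:cap]:
            new_visited = visited | {v} if v in segs else visited
            dfs(v, new_visited, used | {(node, v, key)},
                vseq + [v], eseq + [(node, v, key)])

    dfs(graph.start_vertex, frozenset({graph.start_vertex}), frozenset(),
        [graph.start_vertex], [])

    def dedupe(paths: list[GraphPath]) -> list[GraphPath]:
        # two walks differing only in which parallel edge leaves a
        # junction yield the same contour; key on the entry ports
        seen = set()
        out = []
        for p in paths:
            ports = []
            for (u, v, key), nxt in zip(p.edge_sequence,
                                        p.vertex_sequence[1:]):
                if nxt in segs:
                    ports.append(g.get_edge_data(u, v, key).get("port"))
            sig = (tuple(p.vertex_sequence), tuple(ports))
            if sig not in seen:
                seen.add(sig)
                out.append(p)
        return out

    if results:
        return dedupe(results)
    if fallback:
        return dedupe(fallback)
    raise UnresolvableFrameError("no admissible path from start to end")


# --------------------------------------------------------------------------
# path -> contour
# --------------------------------------------------------------------------

def _order_from(pixels: np.ndarray, entry: tuple[int, int]) -> np.ndarray:
    """Order a segment's pixels by geodesic distance from the entry pixel."""
    if len(pixels) == 1:
        return pixels
    dist = geodesic_distances(pixels, entry)
    return pixels[np.argsort(dist, kind="stable")]


def _nearest_pixel(pixels: np.ndarray, point: tuple[int, int]) -> tuple[int, int]:
    d = np.hypot(pixels[:, 0] - point[0], pixels[:, 1] - point[1])
    return tuple(pixels[int(np.argmin(d))])


def _bridge_curve(before: np.ndarray, after: np.ndarray,
                  n_samples: int = 24) -> np.ndarray:
    """Catmull-Rom interpolant across a junction.

    ``before`` are the last contour points entering the junction and
    ``after`` the first points of the segment leaving it; the bridge
    joins before[-1] to after[0] with tangents taken from the flanking
    context, approximating the strand's true course through the fused
    crossing region.
    """
    p1 = before[-1].astype(float)
    p2 = after[0].astype(float)
    p0 = before[max(-len(before), -4)].astype(float)
    p3 = after[min(len(after) - 1, 3)].astype(float)
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    # standard Catmull-Rom basis (tension 0.5)
    out = (0.5 * ((2 * p1) + (-p0 + p2) * t
                  + (2 * p0 - 5 * p1 + 4 * p2 - p3) * t ** 2
                  + (-p0 + 3 * p1 - 3 * p2 + p3) * t ** 3))
    return out


def _junction_traversal(pixels: np.ndarray, before: np.ndarray,
                        after: np.ndarray | None,
                        entry: tuple[int, int]) -> np.ndarray:
    """Pixels of one crossing of a junction group, in travel order.

    The crossing is modelled by a bridge interpolant from the incoming
    to the outgoing strand; junction pixels within a corridor of the
    bridge are kept, ordered by their position along it.  With no
    outgoing strand (walk ends in the junction) pixels are ordered by
    distance from the entry point.
    """
    if after is None or len(before) == 0:
        e = np.asarray(entry, dtype=float)
        d = np.hypot(pixels[:, 0] - e[0], pixels[:, 1] - e[1])
        return pixels[np.argsort(d, kind="stable")]
    bridge = _bridge_curve(before, after)
    diff = pixels[:, None, :].astype(float) - bridge[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    nearest = dist.min(axis=1)
    keep = nearest <= _JUNCTION_CORRIDOR_PX
    if not keep.any():
        keep = nearest == nearest.min()
    sel = pixels[keep]
    pos = dist[keep].argmin(axis=1)
    return sel[np.argsort(pos, kind="stable")]


def path_to_contour(graph: FilamentGraph, path: GraphPath) -> PixelContour:
    """Concatenate a walk's vertex pixels into an ordered contour.

    Segment pixels are ordered by geodesic distance from the pixel at
    which the walk enters the segment.  Junction-group pixels are
    inserted at every crossing: each traversal keeps the group pixels
    lying along the strand's course (a bridge interpolant between the
    flanking segments) so a group crossed twice contributes its pixels
    to the pass they belong to.
    """
    # first pass: ordered pixels of each segment visit
    seg_ordered: dict[int, np.ndarray] = {}
    entry: tuple[int, int] = graph.start_pixel
    for i, node in enumerate(path.vertex_sequence):
        exit_port = None
        if i < len(path.edge_sequence):
            u, v, key = path.edge_sequence[i]
            exit_port = graph.graph.get_edge_data(u, v, key).get("port")
        if graph.kind_of(node) == "segment":
            ordered = _order_from(graph.pixels_of(node),
                                  _nearest_pixel(graph.pixels_of(node), entry))
            seg_ordered[i] = ordered
            tail = tuple(ordered[-1])
        else:
            tail = entry
        if exit_port is not None and i + 1 < len(path.vertex_sequence) \
                and graph.kind_of(path.vertex_sequence[i + 1]) == "segment":
            entry = exit_port
        else:
            entry = tail
    # second pass: assemble, bridging junction groups between segments
    pts: list[np.ndarray] = []
    for i, node in enumerate(path.vertex_sequence):
        if graph.kind_of(node) == "segment":
            pts.append(seg_ordered[i])
        else:
            before = seg_ordered.get(i - 1)
            after = seg_ordered.get(i + 1)
            if before is None:
                before = np.asarray([graph.start_pixel])
            prev_tail = tuple(pts[-1][-1]) if pts else graph.start_pixel
            pts.append(_junction_traversal(graph.pixels_of(node), before,
                                           after, prev_tail))
    return PixelContour(np.vstack(pts))


# --------------------------------------------------------------------------
# DTW scoring
# --------------------------------------------------------------------------

def dtw_score(contour: PixelContour | np.ndarray,
              template: PixelContour | np.ndarray) -> float:
    """Dynamic-time-warping alignment cost between two 2-D contours.

    Cumulative cost D(i, j) = d(S_i, R_j) + min(D(i-1, j-1),
    D(i-1, j), D(i, j-1)) with Euclidean local cost, D(0, 0) equal to
    the first pair's distance and out-of-range terms infinite; returns
    D(n-1, m-1).
    """
    a = contour.points.astype(float) if isinstance(contour, PixelContour) \
        else np.asarray(contour, dtype=float)
    b = template.points.astype(float) if isinstance(template, PixelContour) \
        else np.asarray(template, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("contours must be non-empty")
    diff = a[:, None, :] - b[None, :, :]
    cost = np.sqrt((diff ** 2).sum(axis=2))
    n, m = cost.shape
    prev = np.cumsum(cost[0])  # row 0: only horizontal accumulation
    for i in range(1, n):
        c = cost[i]
        # a[j] = best predecessor from the previous row
        amin = np.empty(m)
        amin[0] = prev[0]
        if m > 1:
            amin[1:] = np.minimum(prev[:-1], prev[1:])
        # D[i, j] = min_{k<=j} (amin[k] + sum(c[k..j])) via prefix sums
        s = np.cumsum(c)
        shifted = np.concatenate(([0.0], s[:-1]))
        prev = s + np.minimum.accumulate(amin - shifted)
    return float(prev[-1])


# --------------------------------------------------------------------------
# frame resolution and tracking
# --------------------------------------------------------------------------

def resolve_frame(skeleton: Skeleton,
                  template: TemplateState | None,
                  start: tuple[int, int],
                  cap: int = 10,
                  max_paths: int = 100) -> tuple[PixelContour, dict]:
    """Resolve one frame to an ordered contour.

    Unbranched skeletons are ordered directly (the template is not
    consulted).  Branched skeletons are mapped to a graph, candidate
    paths enumerated, and the path with minimal DTW score against the
    template selected (ties: first in enumeration order).  Returns the
    contour and a diagnostics dict.
    """
    info: dict = {"n_branch_pixels": len(find_branch_pixels(skeleton))}
    if info["n_branch_pixels"] == 0:
        contour = order_unbranched(skeleton, start)
        info.update(n_paths=1, dtw=None, branched=False)
        return contour, info
    if template is None:
        raise UnresolvableFrameError(
            "branched frame with no template available")
    graph = build_graph(skeleton, start=start)
    keys = select_key_vertices(graph, template)
    paths = enumerate_paths(graph, keys, cap=cap, max_paths=max_paths,
                            template=template)
    best_contour = None
    best_score = np.inf
    for p in paths:
        contour = path_to_contour(graph, p)
        score = dtw_score(contour, template.contour)
        if score < best_score:
            best_score = score
            best_contour = contour
    info.update(n_paths=len(paths), dtw=best_score, branched=True)
    return best_contour, info


def _override_contour(skeleton: Skeleton, start: tuple[int, int],
                      override: ManualOverride) -> PixelContour:
    """Convert a manual vertex-label sequence into a contour."""
    graph = build_graph(skeleton, start=start)
    seq = list(override.region_sequence)
    if not seq or seq[0] != graph.start_vertex:
        raise ValueError(
            f"override for frame {override.frame_index} must start at "
            f"vertex {graph.start_vertex}")
    edges: list[tuple[int, int, int]] = []
    used: set[tuple[int, int, int]] = set()
    pos = graph.start_pixel
    for u, v in zip(seq[:-1], seq[1:]):
        data = graph.graph.get_edge_data(u, v)
        if not data:
            raise ValueError(f"no edge between vertices {u} and {v}")
        # among parallel edges pick the unused one nearest the running end
        best_key, best_d = None, np.inf
        for key, attrs in data.items():
            if (u, v, key) in used:
                continue
            port = attrs.get("port", tuple(graph.pixels_of(v)[0]))
            d = float(np.hypot(port[0] - pos[0], port[1] - pos[1]))
            if d < best_d:
                best_key, best_d = key, d
        if best_key is None:
            raise ValueError(f"edge between {u} and {v} already consumed")
        used.add((u, v, best_key))
        edges.append((u, v, best_key))
        attrs = graph.graph.get_edge_data(u, v, best_key)
        pos = attrs.get("port", pos)
    return path_to_contour(graph, GraphPath(seq, edges))


def _nearest_endpoint(skeleton: Skeleton,
                      point: tuple[float, float]) -> tuple[int, int]:
    eps = find_endpoints(skeleton)
    if not eps:
        raise UnresolvableFrameError("skeleton has no endpoints")
    arr = np.array(eps)
    d = np.hypot(arr[:, 0] - point[0], arr[:, 1] - point[1])
    return tuple(arr[int(np.argmin(d))])


def track_series(skeletons: list[Skeleton],
                 config: TrackConfig | None = None,
                 overrides: list[ManualOverride] | None = None) -> Track:
    """Resolve a full time series with template and start propagation.

    Frame 0 must be unbranched (or carry an override).  After each
    successful resolution the template becomes that frame's contour
    (or, in ``last_unbranched`` mode, only unbranched contours update
    it); the next frame's start is its skeleton endpoint nearest the
    previous start.  Frames that fail without an override are flagged
    in ``Track.skipped`` and the template retained.
    """
    config = config or TrackConfig()
    by_frame = {o.frame_index: o for o in (overrides or [])}
    contours: list[PixelContour | None] = []
    infos: list[dict] = []
    skipped: list[int] = []
    template: TemplateState | None = None
    prev_start: tuple[float, float] | None = None

    for k, skel in enumerate(skeletons):
        if prev_start is None:
            seed = config.start_xy
            if seed is not None:
                seed_rc = (seed[1], seed[0])  # (x, y) -> (row, col)
            else:
                seed_rc = tuple(find_endpoints(skel)[0]) if find_endpoints(skel) \
                    else tuple(skel.pixels[0])
        else:
            seed_rc = prev_start
        try:
            start = _nearest_endpoint(skel, seed_rc)
        except UnresolvableFrameError:
            contours.append(None)
            infos.append({"error": "no endpoints"})
            skipped.append(k)
            continue

        try:
            if k in by_frame:
                contour = _override_contour(skel, start, by_frame[k])
                info = {"override": True, "branched": True}
            else:
                contour, info = resolve_frame(
                    skel, template, start,
                    cap=config.path_cap, max_paths=config.max_paths)
        except UnresolvableFrameError as exc:
            if k == 0:
                raise UnresolvableFrameError(
                    "frame 0 is branched and no override was supplied"
                ) from exc
            contours.append(None)
            infos.append({"error": str(exc)})
            skipped.append(k)
            continue

        contours.append(contour)
        infos.append(info)
        prev_start = tuple(contour.points[0])
        update = (config.template_mode == "last_resolved"
                  or not info.get("branched", False))
        if update:
            template = TemplateState(contour, frame_index=k)
        elif template is None and not info.get("branched", False):
            template = TemplateState(contour, frame_index=k)
    return Track(contours=contours, skipped=skipped, info=infos)
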