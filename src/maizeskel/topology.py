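"""Skeleton graph construction: k-nearest-neighbor connection, closed-loop
breaking, and stem/leaf segmentation.

Key points are connected to at most three neighbors (maize has a single
unbranched stem with simple leaves, so no skeleton node needs more). The
resulting graph can contain spurious triangle or polygon loops; each loop
is broken by deleting its worst edge under a combined weight: how far the
edge's endpoints sit from the loop's best-fit plane (skeleton loops are
nearly coplanar) plus how sharply the edge turns against its neighbors
(real skeleton edges continue smoothly along the growth direction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

__all__ = [
    "SkeletonGraph",
    "PlantSkeleton",
    "connect_knn",
    "ensure_connected",
    "plane_fit",
    "break_loops",
    "segment_stem_leaves",
]


@dataclass
class SkeletonGraph:
    """Undirected graph over key-point positions (edges as index pairs)."""

    nodes: np.ndarray
    edges: list[tuple[int, int]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        for i, j in self.edges:
            g.add_edge(i, j, length=float(np.linalg.norm(self.nodes[i] - self.nodes[j])))
        return g

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def is_tree(self) -> bool:
        g = self.to_networkx()
        return nx.is_connected(g) and g.number_of_edges() == g.number_of_nodes() - 1


@dataclass
class PlantSkeleton:
    """Semantic skeleton: stem polyline plus ordered leaf polylines.

    ``stem`` runs from the base upward. Each leaf polyline starts at its
    growth point, which is the stem node ``stem[growth_index[i]]``.
    ``stem_ids`` / ``leaf_ids`` carry the originating key-point index of
    every polyline node (-1 for nodes created later by calibration).
    """

    stem: np.ndarray
    leaves: list[np.ndarray]
    growth_index: list[int]
    stem_ids: np.ndarray = field(default=None, repr=False)
    leaf_ids: list[np.ndarray] = field(default=None, repr=False)
    base_tangents: list = field(default=None, repr=False)
    """Optional per-leaf unit base-tangent vectors estimated during
    calibration directly from the blade surface (None where unknown)."""

    def __post_init__(self) -> None:
        if self.stem_ids is None:
            self.stem_ids = np.full(len(self.stem), -1, dtype=int)
        if self.leaf_ids is None:
            self.leaf_ids = [np.full(len(p), -1, dtype=int) for p in self.leaves]
        if self.base_tangents is None:
            self.base_tangents = [None] * len(self.leaves)

    @property
    def base(self) -> np.ndarray:
        return self.stem[0]

    @property
    def growth_points(self) -> np.ndarray:
        return np.asarray([self.stem[g] for g in self.growth_index]).reshape(-1, 3)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def all_positions(self) -> np.ndarray:
        return np.vstack([self.stem] + [p[1:] for p in self.leaves if len(p) > 1]) \
            if self.leaves else self.stem

    def to_json_dict(self) -> dict:
        return {
            "stem": self.stem.tolist(),
            "leaves": [p.tolist() for p in self.leaves],
            "growth_index": list(map(int, self.growth_index)),
        }


def connect_knn(positions: np.ndarray, k: int = 3) -> SkeletonGraph:
    """Connect each key point to at most ``k`` (default 3) neighbors.

    Every node proposes edges to its k nearest neighbors; proposed edges
    are admitted in ascending length order as long as both endpoints stay
    at degree <= k. The result may contain cycles.
    """
    P = np.asarray(positions, dtype=np.float64)
    n = len(P)
    if n < 2:
        raise ValueError("need at least 2 key points")
    kk = min(k, n - 1)
    tree = cKDTree(P)
    _, nbr = tree.query(P, k=kk + 1)
    proposals = set()
    for i in range(n):
        for j in nbr[i, 1:]:
            proposals.add((min(i, int(j)), max(i, int(j))))
    cand = sorted(proposals,
                  key=lambda e: (float(np.linalg.norm(P[e[0]] - P[e[1]])), e))
    deg = np.zeros(n, dtype=int)
    edges: list[tuple[int, int]] = []
    for i, j in cand:
        if deg[i] < k and deg[j] < k:
            edges.append((i, j))
            deg[i] += 1
            deg[j] += 1
    return SkeletonGraph(P.copy(), edges)


def ensure_connected(
    graph: SkeletonGraph,
    source_points: list[np.ndarray] | None = None,
) -> SkeletonGraph:
    """Bridge disconnected components with their most plausible linking edges.

    The degree cap of the k-NN connection can strand short tip chains
    (e.g. the bunched key points of a strongly drooping leaf tip). When
    ``source_points`` is given — per key point, the contracted-cloud
    points it absorbed — stranded components are reattached where their
    absorbed point sets are closest, i.e. along the underlying contracted
    curve rather than across free space between different organs.
    Otherwise key-point centroid distance is used.
    """
    g = graph.to_networkx()
    comps = [np.asarray(sorted(c)) for c in nx.connected_components(g)]
    if len(comps) == 1:
        return graph
    log.info("bridging %d disconnected skeleton components", len(comps))

    def node_cloud(i: int) -> np.ndarray:
        if source_points is not None and len(source_points[i]):
            return np.asarray(source_points[i])
        return graph.nodes[i][None, :]

    edges = list(graph.edges)
    main = list(comps[0])
    rest = [list(c) for c in comps[1:]]
    while rest:
        main_clouds = [node_cloud(i) for i in main]
        tree = cKDTree(np.vstack(main_clouds))
        owner = np.repeat(main, [len(c) for c in main_clouds])
        best = None
        for ci, comp in enumerate(rest):
            for u in comp:
                d, idx = tree.query(node_cloud(u))
                a = int(np.argmin(d))
                cand = (float(d[a]), int(u), int(owner[idx[a]]), ci)
                if best is None or cand < best:
                    best = cand
        _, u, v, ci = best
        edges.append((min(u, v), max(u, v)))
        main.extend(rest.pop(ci))
    return SkeletonGraph(graph.nodes, edges)


def plane_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares plane through >= 3 points.

    Returns ``(coeffs, e)`` with coeffs = (a, b, c, d) describing
    ax + by + cz + d = 0 with unit normal, and e the sum of squared
    orthogonal distances. Collinear input raises ValueError.
    """
    P = np.asarray(points, dtype=np.float64)
    if len(P) < 3:
        raise ValueError("need at least 3 points")
    centroid = P.mean(axis=0)
    centered = P - centroid
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    scale = np.linalg.norm(centered)
    if sv[1] <= 1e-12 * max(sv[0], 1e-300) or scale == 0:
        raise ValueError("degenerate plane: points are collinear")
    normal = vt[2]
    d = -float(normal @ centroid)
    e = float(sv[2] ** 2)
    return np.append(normal, d), e


def _shortest_cycle(g: nx.Graph) -> list[int] | None:
    """Shortest (fewest-edge) cycle, tie-broken by lowest node sequence."""
    best: tuple[int, list[int]] | None = None
    for u, v in sorted(g.edges()):
        g.remove_edge(u, v)
        try:
            path = nx.shortest_path(g, u, v)
        except nx.NetworkXNoPath:
            path = None
        g.add_edge(u, v)
        if path is not None:
            key = (len(path), sorted(path))
            if best is None or key < (len(best[1]), sorted(best[1])):
                best = (len(path), path)
    return None if best is None else best[1]


def _cycle_edge_weights(positions: np.ndarray, cycle: list[int]) -> np.ndarray:
    """Combined coplanarity + growth-direction weight per cycle edge.

    Edge i joins cycle[i] and cycle[i+1] (cyclically). W_s is the sum of
    its endpoints' distances to the cycle's best-fit plane; W_c the sum of
    the turning angles (radians) at its endpoints between consecutive
    cycle edges. Each term is normalized by its maximum over the cycle.
    """
    m = len(cycle)
    pts = positions[cycle]
    try:
        coeffs, _ = plane_fit(pts)
        dist = np.abs(pts @ coeffs[:3] + coeffs[3])
    except ValueError:
        dist = np.zeros(m)
    # turning angle at each cycle vertex
    prev_dir = pts - np.roll(pts, 1, axis=0)
    next_dir = np.roll(pts, -1, axis=0) - pts
    pn = np.linalg.norm(prev_dir, axis=1)
    nn = np.linalg.norm(next_dir, axis=1)
    denom = np.where(pn * nn > 0, pn * nn, 1.0)
    cos = np.clip(np.einsum("ij,ij->i", prev_dir, next_dir) / denom, -1, 1)
    alpha = np.arccos(cos)
    w_s = dist + np.roll(dist, -1)          # endpoints of edge i: v_i, v_{i+1}
    w_c = alpha + np.roll(alpha, -1)
    out = np.zeros(m)
    if w_s.max() > 0:
        out += w_s / w_s.max()
    if w_c.max() > 0:
        out += w_c / w_c.max()
    return out


def break_loops(graph: SkeletonGraph) -> SkeletonGraph:
    """Delete the worst edge of every closed loop until the graph is a tree.

    Loops are processed shortest-first; within a loop the deleted edge
    maximizes the normalized coplanarity + turning-angle weight. Only loop
    edges are ever deleted, so connectivity is preserved.
    """
    g = graph.to_networkx()
    if not nx.is_connected(g):
        raise ValueError("graph must be connected before loop breaking")
    while g.number_of_edges() > g.number_of_nodes() - 1:
        cycle = _shortest_cycle(g)
        if cycle is None:  # pragma: no cover - cannot happen while |E|>=|V|
            break
        w = _cycle_edge_weights(graph.nodes, cycle)
        i = int(np.argmax(w))
        u, v = cycle[i], cycle[(i + 1) % len(cycle)]
        g.remove_edge(u, v)
    edges = [(min(u, v), max(u, v)) for u, v in g.edges()]
    return SkeletonGraph(graph.nodes, sorted(edges))


def _trace_stem(g: nx.Graph, P: np.ndarray, base: int,
                direction_memory: int = 4, lookahead: int = 7) -> list[int]:
    """Follow the stem from the base, preferring straight continuation.

    The reference direction is the mean of the last few stem segment
    directions blended with a standing vertical prior (junction corridors
    bend the recent segments toward the departing leaf, while the stem's
    large-scale course stays near vertical). At a junction each branch is
    scored by the maximum progress along that direction achievable within
    ``lookahead`` edges, computed exactly over the tree: a leaf branch
    tops out at its apex and a dead-end stub runs out of edges, while the
    true stem keeps climbing.
    """

    def best_progress(prev: int, cur: int, direction: np.ndarray,
                      depth: int) -> float:
        if depth == 0:
            return 0.0
        best = 0.0
        for n in g[cur]:
            if n == prev:
                continue
            gain = float((P[n] - P[cur]) @ direction) \
                + best_progress(cur, n, direction, depth - 1)
            if gain > best:
                best = gain
        return best

    path = [base]
    seg_dirs: list[np.ndarray] = [np.array([0.0, 0.0, 1.0])]
    prev = None
    cur = base
    while True:
        nxt_candidates = [n for n in g[cur] if n != prev]
        if not nxt_candidates:
            break
        # reference direction: the stem's accumulated course (base-to-here
        # chord, immune to local junction-corridor bends) blended with a
        # standing vertical prior
        chord = P[cur] - P[base]
        norm = np.linalg.norm(chord)
        if norm > 0.1:
            direction = chord / norm
        else:
            direction = np.mean(seg_dirs[-direction_memory:], axis=0)
            dn = np.linalg.norm(direction)
            direction = direction / dn if dn > 0 else np.array([0.0, 0.0, 1.0])
        direction = direction + np.array([0.0, 0.0, 1.0])
        direction = direction / np.linalg.norm(direction)
        if len(nxt_candidates) == 1:
            nxt = nxt_candidates[0]
        else:
            scores = [
                float((P[n] - P[cur]) @ direction)
                + best_progress(cur, n, direction, lookahead - 1)
                for n in nxt_candidates
            ]
            nxt = nxt_candidates[int(np.argmax(scores))]
        step = P[nxt] - P[cur]
        norm = np.linalg.norm(step)
        if norm > 0:
            seg_dirs.append(step / norm)
        path.append(nxt)
        prev, cur = cur, nxt
    return path


def _component_polylines(
    g: nx.Graph, P: np.ndarray, comp_nodes: set[int], entry: int
) -> list[list[int]]:
    """Decompose an off-stem tree component into polylines from ``entry``.

    The main polyline is the longest (arc-length) path from the entry; any
    side branches are emitted recursively as further polylines rooted where
    they leave the main one.
    """
    sub = g.subgraph(comp_nodes)
    lengths = nx.single_source_dijkstra_path_length(sub, entry, weight="length")
    far = max(lengths, key=lambda n: (lengths[n], -n))
    main = nx.shortest_path(sub, entry, far)
    polylines = [main]
    on_main = set(main)
    remaining = comp_nodes - on_main
    if remaining:
        # each leftover sub-component hangs off exactly one main-path node
        for sub_comp in [set(c) for c in
                         nx.connected_components(g.subgraph(remaining))]:
            attach = start = None
            for n in sub_comp:
                hits = [nb for nb in g[n] if nb in on_main]
                if hits:
                    attach, start = hits[0], n
                    break
            if attach is None:  # pragma: no cover - tree structure guarantees
                continue
            branch = _component_polylines(g, P, sub_comp, start)
            polylines.append([attach] + branch[0])
            polylines.extend(branch[1:])
    return polylines


def segment_stem_leaves(graph: SkeletonGraph) -> PlantSkeleton:
    """Split a skeleton tree into one stem polyline and leaf polylines.

    The base is the lowest degree-1 node; the stem follows the most
    vertically aligned continuation at every junction. Every branch off the
    stem becomes a leaf polyline whose first node (growth point) is the
    stem node it leaves from. Leaves are ordered by growth-point height.
    """
    g = graph.to_networkx()
    P = graph.nodes
    if len(P) < 2:
        raise ValueError("need at least 2 nodes")
    if not nx.is_connected(g) or g.number_of_edges() != len(P) - 1:
        raise ValueError("segmentation requires a spanning tree")
    leaf_nodes = [n for n in g.nodes if g.degree[n] == 1]
    base = min(leaf_nodes, key=lambda n: (P[n][2], n))
    stem_path = _trace_stem(g, P, base)
    stem_set = set(stem_path)
    stem_rank = {n: i for i, n in enumerate(stem_path)}

    leaves: list[np.ndarray] = []
    leaf_ids: list[np.ndarray] = []
    growth_index: list[int] = []
    remaining = set(g.nodes) - stem_set
    for comp in [set(c) for c in nx.connected_components(g.subgraph(remaining))] \
            if remaining else []:
        attach = start = None
        for n in comp:
            hits = [nb for nb in g[n] if nb in stem_set]
            if hits:
                attach, start = hits[0], n
                break
        if attach is None:  # pragma: no cover - tree structure guarantees
            continue
        gidx = stem_rank[attach]
        for k, poly in enumerate(_component_polylines(g, P, comp, start)):
            # the first polyline leaves the stem at ``attach``; side branches
            # (rare, usually spurious) already start at their attachment node
            ids = ([attach] + poly) if k == 0 else poly
            leaves.append(P[ids].copy())
            leaf_ids.append(np.asarray(ids, dtype=int))
            growth_index.append(gidx)

    order = np.argsort([P[stem_path[g_]][2] for g_ in growth_index], kind="stable")
    skel = PlantSkeleton(
        stem=P[stem_path].copy(),
        leaves=[leaves[i] for i in order],
        growth_index=[growth_index[i] for i in order],
        stem_ids=np.asarray(stem_path, dtype=int),
        leaf_ids=[leaf_ids[i] for i in order],
    )
    if not skel.leaves:
        log.info("no branches found: stem-only skeleton")
    return skel
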