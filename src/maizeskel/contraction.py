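"""Laplacian contraction of a plant point cloud toward its curve skeleton.

Each iteration solves the stacked least-squares system

    [ W_L * L ]            [    0      ]
    [   W_H   ] P^{t+1} =  [ W_H * P^t ]

where L is a cotangent-weighted Laplacian built over local one-ring
neighborhoods (k nearest neighbors projected onto the PCA tangent plane
and Delaunay-triangulated), W_L a scalar contraction weight and W_H
per-point attraction weights. After each solve W_L grows geometrically
and W_H,i is rescaled by the shrinkage of point i's one-ring length, so
thin structures collapse onto curves while endpoints stay anchored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.spatial import Delaunay, QhullError, cKDTree

from .cloud import ColoredPointCloud

log = logging.getLogger(__name__)

__all__ = ["ContractionConfig", "ContractionState", "build_laplacian", "contract"]


@dataclass
class ContractionConfig:
    k_neighbors: int = 15
    s_l: float = 3.0  # per-iteration growth factor for W_L
    w_l_init: float | None = None  # None -> 1 / (5 * mean one-ring edge length)
    w_l_cap: float = 2048.0
    w_h_init: float = 1.0
    max_iters: int = 20
    converge_ratio: float = 0.01  # stop when one-ring length shrinks < 1 %
    cot_clamp: float = 1.0e4
    degenerate_ratio: float = 1.0e-3  # tangent-plane anisotropy below which
    # a neighborhood counts as collinear and gets uniform weights


@dataclass
class ContractionState:
    """Evolving contraction state; ``positions`` is the contracted cloud."""

    positions: np.ndarray
    original: np.ndarray
    w_l: float
    w_h: np.ndarray
    s0: np.ndarray  # initial per-point one-ring total edge length
    s_t: np.ndarray  # current one-ring total edge length
    laplacian: sparse.csr_matrix
    iterations: int = 0
    converged: bool = False
    total_length_history: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.positions)


def _one_ring_weights(points2d: np.ndarray, clamp: float) -> tuple[np.ndarray, np.ndarray]:
    """Cotangent weights of edges (0, j) in a 2D Delaunay one-ring of vertex 0.

    Returns (neighbor local indices, weights). Raises QhullError on
    degenerate input.
    """
    tri = Delaunay(points2d)
    simplices = tri.simplices
    mask = np.any(simplices == 0, axis=1)
    own = simplices[mask]
    if own.size == 0:
        raise QhullError("center vertex absent from triangulation")
    weights: dict[int, float] = {}
    for simplex in own:
        a, b = [v for v in simplex if v != 0]
        pa, pb, p0 = points2d[a], points2d[b], points2d[0]
        # angle at b faces edge (0, a); angle at a faces edge (0, b)
        for j, opp in ((a, b), (b, a)):
            u = points2d[j] - points2d[opp]
            v = p0 - points2d[opp]
            cross = abs(u[0] * v[1] - u[1] * v[0])
            cot = float(np.dot(u, v)) / cross if cross > 1e-300 else clamp
            weights[j] = weights.get(j, 0.0) + float(np.clip(cot, -clamp, clamp))
    idx = np.fromiter(weights.keys(), dtype=np.int64)
    w = np.fromiter(weights.values(), dtype=np.float64)
    return idx, np.clip(w, -clamp, clamp)


def build_laplacian(
    positions: np.ndarray,
    k: int = 15,
    cot_clamp: float = 1.0e4,
    degenerate_ratio: float = 1.0e-3,
) -> sparse.csr_matrix:
    """Cotangent Laplacian over tangent-plane Delaunay one-rings.

    For each point its k nearest neighbors are projected onto the local PCA
    tangent plane; the 2D Delaunay one-ring supplies cotangent edge weights
    (clamped to ±cot_clamp). Neighborhoods whose in-plane spread is
    essentially one-dimensional fall back to uniform weights. The matrix is
    symmetrized and its diagonal set so every row sums to zero; off-diagonal
    entries are the (positive-dominant) edge weights.
    """
    P = np.asarray(positions, dtype=np.float64)
    n, k = len(P), int(k)
    if k < 4:
        raise ValueError("k must be >= 4")
    if n < k + 1:
        raise ValueError("need at least k+1 points")
    tree = cKDTree(P)
    _, nbr = tree.query(P, k=k + 1)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for i in range(n):
        ids = nbr[i]
        if ids[0] != i:  # duplicate points: make sure self is first
            ids = np.concatenate([[i], ids[ids != i][: k]])
        local = P[ids] - P[ids].mean(axis=0)
        # tangent plane via SVD of the centered neighborhood
        try:
            _, sv, vt = np.linalg.svd(local, full_matrices=False)
        except np.linalg.LinAlgError:  # pragma: no cover - numerical corner
            sv = np.zeros(3)
            vt = np.eye(3)
        if sv[0] <= 0 or sv[1] <= degenerate_ratio * sv[0]:
            j = ids[1:]
            w = np.ones(len(j))
        else:
            p2 = local @ vt[:2].T
            try:
                lidx, w = _one_ring_weights(p2, cot_clamp)
                j = ids[lidx]
            except (QhullError, ValueError):
                j = ids[1:]
                w = np.ones(len(j))
        rows.append(np.full(len(j), i))
        cols.append(j)
        vals.append(w)
    W = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    W = 0.5 * (W + W.T)
    W.setdiag(0)
    W.eliminate_zeros()
    diag = np.asarray(W.sum(axis=1)).ravel()
    L = W - sparse.diags(diag)
    return L.tocsr()


def one_ring_lengths(L: sparse.csr_matrix, positions: np.ndarray) -> np.ndarray:
    """Per-point total edge length over the Laplacian's one-ring pattern."""
    A = L.tocoo()
    mask = A.row != A.col
    r, c = A.row[mask], A.col[mask]
    d = np.linalg.norm(positions[r] - positions[c], axis=1)
    out = np.zeros(len(positions))
    np.add.at(out, r, d)
    return out


def _solve_iteration(
    L: sparse.csr_matrix, P: np.ndarray, w_l: float, w_h: np.ndarray
) -> np.ndarray:
    """Least-squares solve of the stacked system via normal equations."""
    n = len(P)
    WH2 = sparse.diags(w_h**2)
    M = (w_l**2) * (L.T @ L) + WH2
    rhs = WH2 @ P
    lu = splu(M.tocsc())
    out = np.empty_like(P)
    for d in range(3):
        out[:, d] = lu.solve(rhs[:, d])
    return out


def contract(
    cloud: ColoredPointCloud | np.ndarray,
    config: ContractionConfig | None = None,
) -> ContractionState:
    """Iteratively contract a denoised plant cloud onto its skeleton shape.

    Stops when the total one-ring length shrinks by less than
    ``converge_ratio`` in an iteration, or after ``max_iters`` iterations.
    Point count and ordering are preserved throughout.
    """
    cfg = config or ContractionConfig()
    P0 = (
        cloud.positions if isinstance(cloud, ColoredPointCloud) else np.asarray(cloud)
    ).astype(np.float64)
    L = build_laplacian(P0, cfg.k_neighbors, cfg.cot_clamp, cfg.degenerate_ratio)
    s0 = one_ring_lengths(L, P0)
    s0 = np.where(s0 > 0, s0, np.finfo(float).tiny)
    n_edges = max(L.nnz - len(P0), 1)
    mean_edge = float(s0.sum()) / n_edges
    w_l = cfg.w_l_init if cfg.w_l_init is not None else 1.0 / (5.0 * mean_edge)
    w_h = np.full(len(P0), cfg.w_h_init, dtype=np.float64)
    state = ContractionState(
        positions=P0.copy(), original=P0, w_l=w_l, w_h=w_h,
        s0=s0, s_t=s0.copy(), laplacian=L,
    )
    state.total_length_history.append(float(s0.sum()))
    for t in range(1, cfg.max_iters + 1):
        if state.w_l == 0:
            break
        try:
            P_new = _solve_iteration(state.laplacian, state.positions,
                                     state.w_l, state.w_h)
        except RuntimeError:
            log.warning("singular contraction system; flooring W_H and retrying")
            state.w_h = np.maximum(state.w_h, 1.0)
            P_new = _solve_iteration(state.laplacian, state.positions,
                                     state.w_l, state.w_h)
        if not np.all(np.isfinite(P_new)):
            log.warning("non-finite solve at iteration %d; stopping", t)
            break
        state.positions = P_new
        state.iterations = t
        L_new = build_laplacian(P_new, cfg.k_neighbors, cfg.cot_clamp,
                                cfg.degenerate_ratio)
        s_new = one_ring_lengths(L_new, P_new)
        s_new = np.where(s_new > 0, s_new, np.finfo(float).tiny)
        state.laplacian = L_new
        prev_total = state.total_length_history[-1]
        total = float(s_new.sum())
        state.total_length_history.append(total)
        state.s_t = s_new
        state.w_l = min(cfg.s_l * state.w_l, cfg.w_l_cap)
        state.w_h = cfg.w_h_init * state.s0 / s_new
        if prev_total > 0 and (prev_total - total) / prev_total < cfg.converge_ratio:
            state.converged = True
            break
    return state
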