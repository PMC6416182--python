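"""Point-cloud denoising: pot removal by color difference, scan-noise
removal by near-propagation clustering.

The pot filter compares every point against a short list of manually
sampled pot colors using a brightness-ratio × chroma-angle difference
measure D. D is (by construction) invariant to uniform brightness scaling
of a color, so pot shading does not defeat the filter; points with
D below a threshold (0.1) against any sampled pot color are removed.

Scan noise — small drifting clusters from air movement during scanning —
is then removed by clustering the remaining points into connected
components at a radius proportional to the cloud's bounding-box diagonal
and discarding components smaller than half the average local point
density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .cloud import ColoredPointCloud, bbox_diagonal

__all__ = [
    "ClusterSet",
    "color_difference",
    "remove_pot",
    "near_propagation_cluster",
    "density_threshold",
    "drop_small_clusters",
    "denoise_plant",
]

#: fraction of the bounding-box diagonal used as the clustering radius
DEFAULT_RADIUS_FACTOR = 0.012
#: default color-difference threshold below which a point matches a pot color
DEFAULT_POT_THRESHOLD = 0.1
#: number of random probe points for the local-density estimate
DEFAULT_DENSITY_NUM = 10


@dataclass
class ClusterSet:
    """Partition of point indices into spatially connected clusters."""

    clusters: list[np.ndarray]

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters])

    def __len__(self) -> int:
        return len(self.clusters)


def _chroma(rgb: np.ndarray) -> np.ndarray:
    """Mean-centered color vector (r-mu, g-mu, b-mu)."""
    return rgb - rgb.mean(axis=-1, keepdims=True)


def color_difference(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Color difference D between RGB triples (vectorized over ``p``).

    D = 2 |max(eta_p, eta_q)/min(eta_p, eta_q) - 1| * theta where eta is
    the channel mean (brightness) and theta the angle between the two
    mean-centered chroma vectors, rescaled so a right angle maps to 255.
    Pure grays have a zero chroma vector; their angle is taken as 0 by
    convention, so D = 0 against any color of any brightness.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    single = p.ndim == 1
    p2 = np.atleast_2d(p)
    eta_p = p2.mean(axis=1)
    eta_q = q.mean()
    if eta_q <= 0 or np.any(eta_p <= 0):
        raise ValueError("color brightness must be positive (no pure black)")
    ratio = np.maximum(eta_p, eta_q) / np.minimum(eta_p, eta_q)
    cp = _chroma(p2)
    cq = _chroma(q)
    norm_p = np.linalg.norm(cp, axis=1)
    norm_q = np.linalg.norm(cq)
    denom = norm_p * norm_q
    cos = np.clip(np.divide(cp @ cq, denom, out=np.ones_like(denom),
                            where=denom > 0), -1.0, 1.0)
    theta = np.where(denom > 0, np.arccos(cos), 0.0) * 255.0 / (np.pi / 2.0)
    d = 2.0 * np.abs(ratio - 1.0) * theta
    return float(d[0]) if single else d


def remove_pot(
    cloud: ColoredPointCloud,
    noise_colors: np.ndarray,
    threshold: float = DEFAULT_POT_THRESHOLD,
) -> tuple[ColoredPointCloud | None, ColoredPointCloud | None]:
    """Split a cloud into (plant, pot) by color difference.

    A point goes to the pot side iff its minimum D over the sampled pot
    colors is below ``threshold``. Either side may be None when empty.
    """
    noise_colors = np.atleast_2d(np.asarray(noise_colors, dtype=np.float64))
    if noise_colors.size == 0:
        raise ValueError("noise color list must be non-empty")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rgb = cloud.colors.astype(np.float64)
    dmin = np.full(cloud.n, np.inf)
    for q in noise_colors:
        dmin = np.minimum(dmin, color_difference(rgb, q))
    is_pot = dmin < threshold
    pot = cloud.select(is_pot) if is_pot.any() else None
    plant = cloud.select(~is_pot) if (~is_pot).any() else None
    return plant, pot


def near_propagation_cluster(
    cloud: ColoredPointCloud | np.ndarray, r: float
) -> ClusterSet:
    """Cluster points into connected components at linking radius ``r``.

    Equivalent to the propagation scheme of growing each cluster by
    repeated fixed-radius neighbor queries until exhaustion; the resulting
    partition is exactly the connected components of the <= r proximity
    graph, hence independent of seed choice and traversal order.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    pos = cloud.positions if isinstance(cloud, ColoredPointCloud) else np.asarray(cloud)
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r, output_type="ndarray")
    n = len(pos)
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    order = np.argsort(labels, kind="stable")
    bounds = np.searchsorted(labels[order], np.arange(n_comp + 1))
    clusters = [order[bounds[i]:bounds[i + 1]] for i in range(n_comp)]
    return ClusterSet(clusters)


def density_threshold(
    cloud: ColoredPointCloud | np.ndarray,
    r: float,
    num: int = DEFAULT_DENSITY_NUM,
    seed: int = 0,
) -> float:
    """Minimum-cluster-size threshold: half the mean neighborhood count.

    ``num`` probe points are drawn at random (reproducibly via ``seed``);
    density(p, r) counts the points within radius r of probe p, including
    the probe itself.
    """
    if num < 1:
        raise ValueError("num must be >= 1")
    pos = cloud.positions if isinstance(cloud, ColoredPointCloud) else np.asarray(cloud)
    rng = np.random.default_rng(seed)
    n = len(pos)
    probes = rng.choice(n, size=min(num, n), replace=False)
    tree = cKDTree(pos)
    counts = [len(tree.query_ball_point(pos[i], r)) for i in probes]
    return 0.5 * float(np.mean(counts))


def drop_small_clusters(
    clusters: ClusterSet,
    cloud: ColoredPointCloud,
    r: float,
    num: int = DEFAULT_DENSITY_NUM,
    seed: int = 0,
) -> ColoredPointCloud:
    """Remove clusters smaller than the density-based size threshold."""
    thr = density_threshold(cloud, r, num=num, seed=seed)
    keep = [c for c in clusters.clusters if len(c) >= thr]
    if not keep:
        raise ValueError(
            "no plant remains after cluster filtering; radius or input suspect"
        )
    return cloud.select(np.sort(np.concatenate(keep)))


def denoise_plant(
    cloud: ColoredPointCloud,
    pot_colors: np.ndarray | None = None,
    pot_threshold: float = DEFAULT_POT_THRESHOLD,
    radius_factor: float = DEFAULT_RADIUS_FACTOR,
    density_num: int = DEFAULT_DENSITY_NUM,
    seed: int = 0,
) -> ColoredPointCloud:
    """Full denoising stage: pot color filter, then cluster filtering."""
    plant = cloud
    if pot_colors is not None and len(np.atleast_2d(pot_colors)):
        plant, _pot = remove_pot(cloud, pot_colors, pot_threshold)
        if plant is None:
            raise ValueError("pot filter removed every point")
    r = radius_factor * bbox_diagonal(plant)
    clusters = near_propagation_cluster(plant, r)
    return drop_small_clusters(clusters, plant, r, num=density_num, seed=seed)
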