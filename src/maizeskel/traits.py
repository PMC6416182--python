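"""Phenotypic trait estimation from a calibrated plant skeleton.

Six traits, per the standard maize skeleton conventions:

* leaf length — polyline arc length from the growth point to the tip (m);
* leaf inclination angle — angle between the leaf-base tangent and the
  local stem axis (deg);
* leaf top length — arc length from the base to the leaf's highest node (m);
* leaf azimuthal angle — counter-clockwise angle, viewed from above,
  between a leaf's horizontal direction and the lowest leaf's (deg,
  lowest leaf = 0 by convention);
* leaf growth height — vertical distance from the growth point to the
  stem base (m);
* plant height — vertical distance from the highest skeleton node to the
  stem base (m).

``evaluate`` scores a predicted trait table against a reference one
(leaves matched by height rank) with NRMSE (% of the reference mean) and
R² (squared Pearson correlation), the standard accuracy surface for
skeleton-derived phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import PlantSkeleton

__all__ = [
    "TraitTable",
    "leaf_length",
    "top_length",
    "inclination_angle",
    "azimuth_angle",
    "growth_height",
    "plant_height",
    "compute_traits",
    "evaluate",
]

LEAF_TRAITS = ["leaf_length_m", "inclination_deg", "top_length_m",
               "azimuth_deg", "growth_height_m"]


@dataclass
class TraitTable:
    """Per-leaf trait rows (rank 1 = lowest leaf) plus plant height."""

    leaves: pd.DataFrame
    plant_height_m: float
    plant_id: str = "plant"

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


def _arc_lengths(poly: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(np.asarray(poly, float), axis=0), axis=1)


def leaf_length(leaf: np.ndarray) -> float:
    """Arc length of the leaf polyline, base to tip."""
    if len(leaf) < 2:
        raise ValueError("leaf polyline needs >= 2 nodes")
    return float(_arc_lengths(leaf).sum())


def top_length(leaf: np.ndarray) -> float:
    """Arc length from the base to the highest point of the leaf.

    The apex is located at the maximum-z node (first maximum on ties) and
    refined by a parabola through the node and its two neighbors, so the
    estimate does not quantize to the node spacing.
    """
    leaf = np.asarray(leaf, float)
    apex = int(np.argmax(leaf[:, 2]))
    if apex == 0:
        return 0.0
    arcs = np.concatenate([[0.0], np.cumsum(_arc_lengths(leaf))])
    top = arcs[apex]
    if 0 < apex < len(leaf) - 1:
        s = arcs[apex - 1: apex + 2]
        z = leaf[apex - 1: apex + 2, 2]
        denom = (s[0] - s[1]) * (s[0] - s[2]) * (s[1] - s[2])
        if abs(denom) > 1e-15:
            a = (s[2] * (z[1] - z[0]) + s[1] * (z[0] - z[2])
                 + s[0] * (z[2] - z[1])) / denom
            b = (s[2] ** 2 * (z[0] - z[1]) + s[1] ** 2 * (z[2] - z[0])
                 + s[0] ** 2 * (z[1] - z[2])) / denom
            if a < 0:
                vertex = -b / (2.0 * a)
                top = float(np.clip(vertex, s[0], s[2]))
    return float(top)


def _base_tangent(leaf: np.ndarray, base_k: int = 2) -> np.ndarray:
    """Mean direction of the first ``base_k`` segments."""
    leaf = np.asarray(leaf, float)
    segs = np.diff(leaf[: base_k + 1], axis=0)
    norms = np.linalg.norm(segs, axis=1)
    dirs = segs[norms > 0] / norms[norms > 0, None]
    if len(dirs) == 0:
        raise ValueError("degenerate leaf base")
    t = dirs.mean(axis=0)
    return t / np.linalg.norm(t)


def inclination_angle(leaf: np.ndarray, stem_axis: np.ndarray,
                      base_k: int = 2) -> float:
    """Angle (deg) between the leaf-base tangent and the stem axis."""
    axis = np.asarray(stem_axis, float)
    axis = axis / np.linalg.norm(axis)
    cos = float(np.clip(_base_tangent(leaf, base_k) @ axis, -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))


def _horizontal_direction(leaf: np.ndarray) -> np.ndarray:
    """Horizontal projection of the growth-point-to-tip vector."""
    v = np.asarray(leaf[-1], float) - np.asarray(leaf[0], float)
    h = np.array([v[0], v[1]])
    norm = np.linalg.norm(h)
    if norm == 0:
        raise ValueError("leaf has no horizontal extent")
    return h / norm


def azimuth_angle(leaf: np.ndarray, reference_leaf: np.ndarray,
                  tangent: np.ndarray | None = None,
                  reference_tangent: np.ndarray | None = None) -> float:
    """CCW angle from the reference (lowest) leaf's direction, deg in [0, 360).

    A maize leaf lies in a near-vertical plane, so the horizontal
    direction of its base tangent equals the horizontal direction of the
    base-to-tip vector; when a measured base tangent is available it is
    preferred, being immune to a polyline whose far end strayed onto a
    crossing blade.
    """
    def hdir(poly, tan):
        if tan is not None and np.linalg.norm(np.asarray(tan)[:2]) > 1e-9:
            h = np.asarray(tan, float)[:2]
            return h / np.linalg.norm(h)
        return _horizontal_direction(poly)

    a = hdir(leaf, tangent)
    r = hdir(reference_leaf, reference_tangent)
    ang = np.degrees(np.arctan2(a[1], a[0]) - np.arctan2(r[1], r[0]))
    return float(np.mod(ang, 360.0))


def growth_height(leaf: np.ndarray, skeleton: PlantSkeleton) -> float:
    """Vertical distance from the growth point to the stem base."""
    return float(np.asarray(leaf, float)[0, 2] - skeleton.base[2])


def plant_height(skeleton: PlantSkeleton) -> float:
    """Vertical distance from the highest skeleton node to the stem base."""
    return float(skeleton.all_positions()[:, 2].max() - skeleton.base[2])


def _stem_axis_at(skeleton: PlantSkeleton, g: int) -> np.ndarray:
    """Direction of the calibrated stem around stem node ``g`` (points up).

    Fitted over several nodes: two adjacent nodes can straddle a
    millimetric section-boundary kink and tilt by degrees.
    """
    stem = skeleton.stem
    lo = max(g - 3, 0)
    hi = min(g + 4, len(stem))
    pts = stem[lo:hi]
    if len(pts) < 2 or np.allclose(pts, pts[0]):
        return np.array([0.0, 0.0, 1.0])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    v = vt[0]
    return v if v[2] >= 0 else -v


def compute_traits(skeleton: PlantSkeleton, plant_id: str = "plant",
                   base_k: int = 2) -> TraitTable:
    """All six traits for one plant; leaves ranked lowest-first."""
    rows = []
    order = np.argsort([lf[0][2] for lf in skeleton.leaves], kind="stable") \
        if skeleton.leaves else []
    ref_leaf = skeleton.leaves[order[0]] if len(order) else None
    for rank, li in enumerate(order, start=1):
        leaf = skeleton.leaves[li]
        g = skeleton.growth_index[li]
        axis = _stem_axis_at(skeleton, g)
        tangent = skeleton.base_tangents[li] \
            if li < len(skeleton.base_tangents) else None
        if tangent is not None:
            # calibration measured the base tangent directly on the blade
            cos = float(np.clip(np.asarray(tangent) @ axis, -1.0, 1.0))
            incl = float(np.degrees(np.arccos(cos)))
        else:
            incl = inclination_angle(leaf, axis, base_k)
        rows.append({
            "plant_id": plant_id,
            "leaf_rank": rank,
            "leaf_length_m": leaf_length(leaf),
            "inclination_deg": incl,
            "top_length_m": top_length(leaf),
            "azimuth_deg": azimuth_angle(
                leaf, ref_leaf, tangent,
                skeleton.base_tangents[order[0]] if len(order) else None),
            "growth_height_m": growth_height(leaf, skeleton),
        })
    df = pd.DataFrame(rows, columns=["plant_id", "leaf_rank"] + LEAF_TRAITS)
    return TraitTable(df, plant_height(skeleton), plant_id)


def _wrap_degrees(delta: np.ndarray) -> np.ndarray:
    """Signed angular difference folded into (-180, 180]."""
    return (np.asarray(delta, float) + 180.0) % 360.0 - 180.0


def evaluate(pred: list[TraitTable] | TraitTable,
             truth: list[TraitTable] | TraitTable) -> pd.DataFrame:
    """NRMSE (%) and R² of predicted vs reference traits.

    Leaves are matched by height rank within each plant; every plant must
    yield the same leaf count in both tables. Azimuths are compared on the
    circle (differences wrapped to ±180°) since 1° and 359° are the same
    direction. NRMSE is normalized by the mean of the reference values.
    """
    preds = [pred] if isinstance(pred, TraitTable) else list(pred)
    truths = [truth] if isinstance(truth, TraitTable) else list(truth)
    if len(preds) != len(truths):
        raise ValueError("pred and truth must cover the same plants")
    p_rows, t_rows = [], []
    for p, t in zip(preds, truths):
        if p.n_leaves != t.n_leaves:
            raise ValueError(
                f"plant {p.plant_id}: {p.n_leaves} predicted leaves vs "
                f"{t.n_leaves} reference leaves; rank matching impossible"
            )
        p_rows.append(p.leaves.sort_values("leaf_rank"))
        t_rows.append(t.leaves.sort_values("leaf_rank"))
    P = pd.concat(p_rows, ignore_index=True)
    T = pd.concat(t_rows, ignore_index=True)
    report = []
    for trait in LEAF_TRAITS:
        x = T[trait].to_numpy(float)
        y = P[trait].to_numpy(float)
        if trait == "azimuth_deg":
            y = x + _wrap_degrees(y - x)
        report.append(_score(trait, x, y))
    hx = np.array([t.plant_height_m for t in truths], float)
    hy = np.array([p.plant_height_m for p in preds], float)
    report.append(_score("plant_height_m", hx, hy))
    return pd.DataFrame(report).set_index("trait")


def _score(trait: str, x: np.ndarray, y: np.ndarray) -> dict:
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    mean = float(np.mean(x))
    nrmse = 100.0 * rmse / abs(mean) if mean != 0 else np.inf
    if len(x) > 1 and np.std(x) > 0 and np.std(y) > 0:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    else:
        r2 = np.nan
    return {"trait": trait, "n": len(x), "rmse": rmse, "nrmse_pct": nrmse,
            "r2": r2}
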