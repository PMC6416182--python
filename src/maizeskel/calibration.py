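"""Skeleton calibration against the original (denoised) point cloud.

Contraction leaves three systematic defects: stem nodes bent sideways by
the pull of nearby leaves, leaf nodes offset from the vein, and leaf tips
that stop short because end points over-contract inward. Calibration fixes
them using the pre-contraction cloud:

* stem: the leaf growth points split the stem into sections; each
  section's interior nodes fit a total-least-squares 3D line and all the
  section's nodes are projected onto it (the stem of a maize plant is
  piecewise straight between insertions);
* leaves: walking from the blade base along the local tangent, each node
  is replaced by the centroid of the original leaf points inside a thin
  slab perpendicular to the tangent — for a roughly symmetric leaf ribbon
  that centroid sits on the vein;
* tips (and, the same way, the stem's free ends): the cutting plane keeps
  stepping forward past the last node until the slab runs out of points,
  appending centroids, so the polyline reaches the true extremity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .topology import PlantSkeleton

log = logging.getLogger(__name__)

__all__ = ["CalibrationConfig", "fit_line", "calibrate_stem", "calibrate_leaf",
           "calibrate_skeleton"]


@dataclass
class CalibrationConfig:
    slab_half_thickness_factor: float = 0.5  # x the walking step
    step_factor: float = 0.5  # walking/extension step, x mean node spacing
    min_slice_points: int = 3  # a slab with fewer members counts as empty
    local_radius: float | None = None  # slab confined to a ball; None -> auto
    max_extension_steps: int = 400
    extend_stem_ends: bool = True
    refine_bases: bool = True  # recover leaf bases from the junction region


def fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares 3D line: returns (point on line, unit direction)."""
    P = np.asarray(points, dtype=np.float64)
    if len(P) < 2:
        raise ValueError("need at least 2 points")
    centroid = P.mean(axis=0)
    _, _, vt = np.linalg.svd(P - centroid, full_matrices=False)
    return centroid, vt[0]


def _project(points: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    return origin + np.outer((points - origin) @ direction, direction)


def _slab_centroid(
    cloud: np.ndarray,
    center: np.ndarray,
    tangent: np.ndarray,
    half_thickness: float,
    local_radius: float,
    min_points: int,
) -> np.ndarray | None:
    """Centroid of cloud points in a slab perpendicular to ``tangent``.

    Membership is confined to a ball of ``local_radius`` around ``center``
    so the plane cannot pick up a distant fold of the same leaf. Returns
    None when the slab holds fewer than ``min_points`` members.
    """
    rel = cloud - center
    within = np.einsum("ij,ij->i", rel, rel) <= local_radius**2
    if not within.any():
        return None
    axial = rel[within] @ tangent
    members = np.abs(axial) <= half_thickness
    if int(members.sum()) < min_points:
        return None
    return cloud[within][members].mean(axis=0)


def _resample_polyline(poly: np.ndarray, step: float) -> np.ndarray:
    """Arc-length resampling at spacing ``step`` (endpoints preserved)."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        return poly[:1].copy()
    m = max(int(np.round(total / step)), 1)
    targets = np.linspace(0.0, total, m + 1)
    out = np.empty((len(targets), 3))
    for d in range(3):
        out[:, d] = np.interp(targets, arc, poly[:, d])
    return out


def _mean_spacing(poly: np.ndarray) -> float:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return float(seg.mean()) if len(seg) else 0.0


def _despike_polyline(poly: np.ndarray, max_turn_deg: float = 100.0) -> np.ndarray:
    """Remove reversal nodes from a polyline.

    Key points bunch where a drooping blade was sampled densely, and the
    tree path can zigzag through the bunch, revisiting the same stretch
    of vein and inflating the arc length. Interior nodes whose turning
    angle exceeds ``max_turn_deg`` (a genuine vein never bends that
    sharply between adjacent key points) are deleted, worst first.
    """
    pts = [np.asarray(p, float) for p in poly]
    changed = True
    while changed and len(pts) > 2:
        changed = False
        worst, worst_turn = None, max_turn_deg
        for i in range(1, len(pts) - 1):
            a = pts[i] - pts[i - 1]
            b = pts[i + 1] - pts[i]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na == 0 or nb == 0:
                worst, worst_turn = i, 180.0
                break
            turn = np.degrees(np.arccos(np.clip(a @ b / (na * nb), -1, 1)))
            if turn > worst_turn:
                worst, worst_turn = i, turn
        if worst is not None:
            del pts[worst]
            changed = True
    return np.asarray(pts)


def calibrate_leaf(
    leaf: np.ndarray,
    leaf_cloud: np.ndarray,
    config: CalibrationConfig | None = None,
) -> np.ndarray:
    """Calibrate one leaf polyline against its original points.

    The polyline (first node = growth point, held fixed) is resampled at
    the walking step, then each node in turn is replaced by the centroid of
    the original-cloud slab cut perpendicular to the local tangent. Past
    the last node the cutting plane keeps stepping forward until a slab is
    empty, which recovers the missing tip.
    """
    cfg = config or CalibrationConfig()
    leaf = _despike_polyline(np.asarray(leaf, dtype=np.float64))
    if len(leaf) < 2:
        return leaf.copy()
    cloud = np.asarray(leaf_cloud, dtype=np.float64)
    if len(cloud) < cfg.min_slice_points:
        log.warning("leaf cloud empty; leaf returned uncalibrated")
        return leaf.copy()
    step = cfg.step_factor * _mean_spacing(leaf)
    if step <= 0:
        return leaf.copy()
    h = cfg.slab_half_thickness_factor * step
    radius = cfg.local_radius
    if radius is None:
        radius = max(6.0 * h, 2.5 * step)
    nodes = _resample_polyline(leaf, step)
    out = [nodes[0]]
    for i in range(1, len(nodes)):
        tangent = nodes[i] - out[-1]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        centroid = _slab_centroid(cloud, nodes[i], tangent / norm, h,
                                  radius, cfg.min_slice_points)
        out.append(centroid if centroid is not None else nodes[i])
    # forward extension toward the tip
    for _ in range(cfg.max_extension_steps):
        if len(out) < 2:
            break
        tangent = out[-1] - out[-2]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            break
        tangent = tangent / norm
        probe = out[-1] + step * tangent
        centroid = _slab_centroid(cloud, probe, tangent, h, radius,
                                  cfg.min_slice_points)
        if centroid is None:
            break
        if float((centroid - out[-1]) @ tangent) < 0.25 * step:
            break  # plane stopped advancing (or slid backward): the tip
        out.append(centroid)
    return np.asarray(out)


def _extend_end(
    nodes: list[np.ndarray],
    cloud: np.ndarray,
    step: float,
    h: float,
    radius: float,
    min_points: int,
    max_steps: int,
) -> list[np.ndarray]:
    """Extend a polyline end (last two nodes give the direction)."""
    out = list(nodes)
    for _ in range(max_steps):
        tangent = out[-1] - out[-2]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            break
        tangent = tangent / norm
        probe = out[-1] + step * tangent
        centroid = _slab_centroid(cloud, probe, tangent, h, radius, min_points)
        if centroid is None or \
                float((centroid - out[-1]) @ tangent) < 0.25 * step:
            break
        out.append(centroid)
    return out


def _trimmed_stem_points(points: np.ndarray | None,
                         iterations: int = 3) -> np.ndarray | None:
    """Isolate the stem's cylindrical surface by iterative trimming.

    Stem-attributed points include leaf-base ribbons swallowed by the
    junction corridors. Surface points all sit about one stem radius from
    the axis while corridor points reach several radii out, so repeatedly
    fitting a line and dropping points beyond 1.6x the median orthogonal
    residual converges onto the cylinder.
    """
    if points is None or len(points) < 50:
        return None
    pts = np.asarray(points, dtype=np.float64)
    for _ in range(iterations):
        origin, direction = fit_line(pts)
        resid = np.linalg.norm(pts - _project(pts, origin, direction), axis=1)
        keep = resid < 1.6 * np.median(resid) + 1e-9
        if keep.sum() < 50 or keep.all():
            break
        pts = pts[keep]
    return pts


def calibrate_stem(
    skeleton: PlantSkeleton,
    stem_cloud: np.ndarray | None = None,
    config: CalibrationConfig | None = None,
) -> PlantSkeleton:
    """Straighten the stem section-wise and recover its free ends.

    Growth points split the stem into sections; each section's line is
    fitted to its interior nodes (the growth points bounding a section are
    excluded from the fit, since those are exactly the nodes bent by leaf
    attraction) and every node of the section is projected onto the fitted
    line. Sections own their lower bounding growth point, so each node is
    projected exactly once. When a stem cloud is supplied the base and top
    are additionally extended by the cutting-plane walk, recovering the
    over-contracted stem extremities.
    """
    cfg = config or CalibrationConfig()
    stem = skeleton.stem.astype(np.float64).copy()
    n = len(stem)
    if n < 3:
        return skeleton
    gset = sorted(set(skeleton.growth_index))
    boundaries = [0] + [g for g in gset if 0 < g < n - 1] + [n]
    new_stem = stem.copy()
    last_dir = None
    sc = np.asarray(stem_cloud) if stem_cloud is not None and \
        len(np.atleast_2d(stem_cloud)) else None
    trimmed = _trimmed_stem_points(sc) if sc is not None else None
    global_dir = None
    if trimmed is not None and len(trimmed) >= 50:
        _, global_dir = fit_line(trimmed)
        if global_dir[2] < 0:
            global_dir = -global_dir
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        # interior nodes: the section minus its bounding growth points
        fit_nodes = [i for i in range(a, b) if i not in gset]
        origin = direction = None
        if global_dir is not None:
            # section line: robust global axis direction through the
            # centroid of this section's trimmed surface points. Skeleton
            # nodes near a junction are displaced toward the departing
            # leaf and junction corridors pollute raw cloud fits, so the
            # line comes from the iteratively trimmed stem surface.
            z_lo = min(stem[a][2], stem[min(b, n - 1)][2])
            z_hi = max(stem[a][2], stem[min(b, n - 1)][2])
            pts = trimmed[(trimmed[:, 2] > z_lo + 0.01)
                          & (trimmed[:, 2] < z_hi - 0.01)]
            if len(pts) >= 20:
                origin, direction = pts.mean(axis=0), global_dir
        if direction is None:
            if len(fit_nodes) < 2:
                log.info("stem section %d:%d too short to fit; left unchanged",
                         a, b)
                continue
            origin, direction = fit_line(stem[fit_nodes])
        if direction[2] < 0:
            direction = -direction
        owned = np.arange(a, b)
        new_stem[owned] = _project(stem[owned], origin, direction)
        last_dir = (origin, direction)
    # the stem top node belongs to the last section's line
    if last_dir is not None:
        new_stem[-1] = _project(stem[-1:], *last_dir)[0]
    stem_ids = skeleton.stem_ids.copy()
    growth_shift = 0
    if cfg.extend_stem_ends and stem_cloud is not None and len(stem_cloud) > 0:
        step = cfg.step_factor * _mean_spacing(new_stem)
        if step > 0:
            h = cfg.slab_half_thickness_factor * step
            radius = cfg.local_radius or max(6.0 * h, 2.5 * step)
            cloud = np.asarray(stem_cloud, dtype=np.float64)
            top = _extend_end([new_stem[-2], new_stem[-1]], cloud, step, h,
                              radius, cfg.min_slice_points,
                              cfg.max_extension_steps)
            base = _extend_end([new_stem[1], new_stem[0]], cloud, step, h,
                               radius, cfg.min_slice_points,
                               cfg.max_extension_steps)
            n_base = len(base) - 2
            n_top = len(top) - 2
            if n_base or n_top:
                parts = [np.asarray(base[:1:-1])] if n_base else []
                parts.append(new_stem)
                if n_top:
                    parts.append(np.asarray(top[2:]))
                new_stem = np.vstack(parts)
                stem_ids = np.concatenate([
                    np.full(n_base, -1, dtype=int), stem_ids,
                    np.full(n_top, -1, dtype=int),
                ])
                growth_shift = n_base
    out = PlantSkeleton(
        stem=new_stem,
        leaves=[p.copy() for p in skeleton.leaves],
        growth_index=[g + growth_shift for g in skeleton.growth_index],
        stem_ids=stem_ids,
        leaf_ids=[ids.copy() for ids in skeleton.leaf_ids],
    )
    # leaves keep their growth node as first vertex; refresh it
    for i, g in enumerate(out.growth_index):
        out.leaves[i][0] = out.stem[g]
    return out


def _fan_fit_odr(x: np.ndarray, off: np.ndarray, y: np.ndarray,
                 beta0: np.ndarray | None = None) -> np.ndarray | None:
    """Orthogonal-distance quadratic fan fit with a blade-sag term.

    Model: y = b0 + b1 x + b2 x^2 + b3 off^2. Ordinary least squares is
    attenuated by sensor noise in x (errors-in-variables), which flattens
    the recovered base tangent; orthogonal-distance regression removes
    that bias. The off^2 regressor absorbs the transverse sag of the
    blade below its midrib.
    """
    from scipy import odr as _odr

    def model(B, xx):
        return B[0] + B[1] * xx[0] + B[2] * xx[0] ** 2 + B[3] * xx[1] ** 2

    if beta0 is None:
        beta0 = list(np.polyfit(x, y, 2)[::-1]) + [-0.5]
    data = _odr.Data(np.stack([x, off]), y)
    out = _odr.ODR(data, _odr.Model(model), beta0=np.asarray(beta0, float),
                   maxit=30).run()
    beta = out.beta
    return beta if np.all(np.isfinite(beta)) else None


def _refine_leaf_base(
    leaf: np.ndarray,
    organ_cloud: np.ndarray,
    junction_cloud: np.ndarray,
    full_cloud: np.ndarray,
    stem: np.ndarray,
    growth_index: int,
    config: CalibrationConfig,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Reconstruct a leaf's base arc from the junction-region points.

    Contraction merges the first ~10 cm of each leaf into the stem, so
    the calibrated polyline only picks up the vein well beyond the true
    attachment: the apparent growth point sits too high and the first
    segment leaves almost horizontally. The missing base is still present
    in the denoised cloud (its points were absorbed by the junction
    region) and is recovered as follows:

    * mask out the stem's own cylindrical surface; with the stem removed,
      the connected component of the remaining points that contains this
      leaf's own points is exactly the leaf's surface — organs only touch
      each other through the stem;
    * near the insertion a maize leaf lies in a vertical plane through
      the stem axis and its width spreads perpendicular to that plane, so
      in in-plane coordinates (radial distance x from the stem, height y
      along it) the component's base points collapse onto the vein. An
      orthogonal-distance quadratic y(x) with a transverse-sag term,
      evaluated at x = 0, gives the growth point on the stem line;
    * nodes sampled from the fitted arc replace the unreliable inner
      polyline up to the first trustworthy outer node.
    """
    if len(leaf) < 4 or len(organ_cloud) < 5 * config.min_slice_points:
        return leaf, None
    g = stem[growth_index]
    # local stem direction over a longer span: two adjacent nodes can
    # straddle a millimetric section-boundary kink and tilt by degrees
    lo, hi = max(growth_index - 3, 0), min(growth_index + 4, len(stem))
    if hi - lo < 2:
        return leaf, None
    _, d = fit_line(stem[lo:hi])
    if d[2] < 0:
        d = -d
    base_cloud = np.vstack([organ_cloud, junction_cloud]) \
        if len(junction_cloud) else np.asarray(organ_cloud)
    n_organ = len(organ_cloud)
    # local stem segment around the junction, densified, for distance tests
    a = max(growth_index - 3, 0)
    b = min(growth_index + 4, len(stem))
    stem_tree = cKDTree(_resample_polyline(stem[a:b], 0.01))
    dist_to_stem = stem_tree.query(base_cloud)[0]
    core = dist_to_stem[dist_to_stem < 0.05]
    r_stem = float(np.median(core)) if len(core) else 0.015
    exclude = r_stem + 0.010
    off_mask = dist_to_stem > exclude
    off_stem = base_cloud[off_mask]
    if len(off_stem) < 5 * config.min_slice_points:
        return leaf, None
    # this leaf's surface: the off-stem connected component holding its
    # own organ points nearest the stem
    comp_labels = _components(off_stem, radius=0.02)
    organ_off = np.nonzero(off_mask[:n_organ])[0]
    if len(organ_off) == 0:
        return leaf, None
    organ_pos = np.nonzero(off_mask)[0]
    organ_in_off = np.searchsorted(organ_pos, organ_off)
    # the leaf's base surface: among components holding a meaningful share
    # of the leaf's own points, the one that reaches closest to the stem
    counts = np.bincount(comp_labels[organ_in_off])
    eligible = np.nonzero(counts >= max(10, 0.1 * len(organ_in_off)))[0]
    if len(eligible) == 0:
        eligible = np.array([counts.argmax()])
    off_dist = dist_to_stem[off_mask]
    seed_label = int(min(eligible,
                         key=lambda c: off_dist[comp_labels == c].min()))
    blade = off_stem[comp_labels == seed_label]
    if len(blade) < 5 * config.min_slice_points:
        return leaf, None
    # in-plane fan coordinates; azimuth from the blade's base region
    rel_blade = blade - g
    base_region = rel_blade[np.linalg.norm(
        rel_blade - np.outer(rel_blade @ d, d), axis=1) < 0.25]
    if len(base_region) < 5:
        return leaf, None
    mean_dir = base_region.mean(axis=0)
    u = mean_dir - (mean_dir @ d) * d
    if np.linalg.norm(u) < 1e-9:
        return leaf, None
    u = u / np.linalg.norm(u)
    m = np.cross(d, u)
    x = rel_blade @ u
    y = rel_blade @ d
    off = rel_blade @ m
    x_hi = 0.14
    x_lo = max(exclude + 0.002, 0.026)
    # wedge window: a maize leaf inserts at >= ~15 degrees from the stem,
    # so its base arc stays below y = x cot(15 deg); anything higher in
    # the sector belongs to an upper leaf passing through
    sel = (x > x_lo) & (x <= x_hi) & (np.abs(off) < 0.025) \
        & (y < 3.7 * x + 0.02) & (y > -0.25)
    if sel.sum() < 25 or np.ptp(x[sel]) < 0.04:
        return leaf, None
    beta = _fan_fit_odr(x[sel], off[sel], y[sel])
    # second stage: extend into the stem-adjacent band with points
    # consistent with the first fit (stem noise stragglers rejected)
    inner = (x > 0.015) & (x <= x_lo) & (np.abs(off) < 0.025)
    if beta is not None and inner.sum() > 3:
        pred = beta[0] + beta[1] * x + beta[2] * x**2 + beta[3] * off**2
        mad = np.median(np.abs((y - pred)[sel])) + 1e-9
        grow = sel | (inner & (np.abs(y - pred) < 3.0 * mad))
        beta2 = _fan_fit_odr(x[grow], off[grow], y[grow], beta)
        beta = beta2 if beta2 is not None else beta
    if beta is None or abs(float(beta[0])) > 0.30:
        return leaf, None
    y0 = float(beta[0])
    poly = np.poly1d([beta[2], beta[1], beta[0]])
    new_growth = g + y0 * d
    # base tangent: ensemble of the local quadratic's slope at x = 0 and
    # a global tilted-arc fit of the sag-corrected blade (the two have
    # opposite truncation biases, so their mean is markedly better than
    # either alone)
    angle_quad = float(np.degrees(np.arctan2(1.0, beta[1])))
    wide = (np.abs(off) < 0.025) & (y > -0.30) & (y < 3.7 * x + 0.05)
    angle_arc = _tilted_arc_angle(x[wide], (y - beta[3] * off**2)[wide])
    angle = angle_quad if angle_arc is None \
        else 0.5 * (angle_quad + angle_arc)
    rad = np.radians(angle)
    tangent = np.sin(rad) * u + np.cos(rad) * d
    step = 0.5 * config.step_factor * _mean_spacing(leaf)
    if step <= 0:
        return leaf, None
    # fan nodes only over the well-supported inner window: the quadratic
    # is an extrapolation device near the stem, not a blade model out to
    # the window edge
    x_fit_max = min(0.10, x_hi, float(np.max(x[sel])))
    xs = np.concatenate([[step / 4.0, step / 2.0],
                         np.arange(step, x_fit_max, step)])
    base_nodes = [g + float(poly(xi)) * d + xi * u for xi in xs]
    if len(base_nodes) < 2:
        return leaf, None
    # trace the rest of the vein directly on the blade surface: on
    # plants with near-planar phyllotaxy the tree polyline can zigzag
    # between overlapping blades, while the cutting-plane walk follows
    # the connected surface
    trace_step = max(0.015, 2.0 * step)
    # trace on the whole plant minus the stem surface: per-organ point
    # attribution has holes where blades cross, and the walk's own
    # guards police which surface it follows
    whole_stem_tree = cKDTree(_resample_polyline(stem, 0.01))
    full_off = full_cloud[whole_stem_tree.query(full_cloud)[0] > exclude]
    traced = _trace_vein(base_nodes, full_off, trace_step,
                         config.slab_half_thickness_factor * trace_step,
                         config.min_slice_points,
                         config.max_extension_steps)
    trace_poly = np.vstack([new_growth[None, :]] + traced)
    # the tree-guided polyline is the alternative reading of the same
    # blade: splice it onto the recovered base
    splice_poly = None
    node_x = (leaf - g) @ u
    beyond = np.nonzero(node_x > x_fit_max)[0]
    if len(beyond):
        splice_poly = np.vstack([new_growth[None, :]] + base_nodes
                                + [leaf[int(beyond[0]):]])
    chosen = _arbitrate_polylines(trace_poly, splice_poly, full_off,
                                  trace_step, config.min_slice_points)
    return chosen, tangent


def _arbitrate_polylines(
    traced: np.ndarray,
    spliced: np.ndarray | None,
    blade: np.ndarray,
    step: float,
    min_points: int,
) -> np.ndarray:
    """Choose between the surface-traced and tree-guided leaf polylines.

    The walk can stall where a crossing blade shadows the slab for too
    long, while the tree polyline can wander onto a crossing blade. When
    the two agree, either will do. When the walk stopped well short of
    the tree polyline, probe past the walk's end: if the blade clearly
    continues there, the walk stalled and the tree polyline wins;
    otherwise the walk reached a genuine tip and the tree polyline is the
    one that wandered.
    """
    if spliced is None:
        return traced
    arc = lambda p: float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())
    if arc(traced) >= 0.8 * arc(spliced):
        return traced
    end = traced[-1]
    tangent = traced[-1] - traced[-2]
    norm = np.linalg.norm(tangent)
    if norm == 0:
        return spliced
    tangent = tangent / norm
    for kstep in (1.0, 2.0, 3.0):
        probe = end + kstep * step * tangent
        rel = blade - probe
        within = np.einsum("ij,ij->i", rel, rel) <= 0.05**2
        count = int(np.sum(np.abs(rel[within] @ tangent) <= step))
        if count >= 2 * min_points:
            return spliced  # rich continuation: the walk stalled
    return traced


def _trace_vein(
    start_nodes: list[np.ndarray],
    blade: np.ndarray,
    step: float,
    h: float,
    min_points: int,
    max_steps: int,
    radius: float = 0.05,
    max_blind: int = 2,
) -> list[np.ndarray]:
    """Walk the cutting plane along a blade from its base to the tip.

    Each step advances by ``step`` along the current tangent and replaces
    the probe with the slab centroid. Where another blade crosses, the
    centroid jerks sideways; such steps (and empty slabs) are taken
    blindly along the tangent instead, up to ``max_blind`` in a row, so
    the walk passes through the crossing without switching blades. The
    walk ends when the slab stays empty or stops advancing — the tip.
    """
    nodes = [np.asarray(p, float) for p in start_nodes]
    blind = 0
    pending: list[np.ndarray] = []
    for _ in range(max_steps):
        cur = pending[-1] if pending else nodes[-1]
        prev = (pending[-2] if len(pending) > 1
                else nodes[-1] if pending else nodes[-2])
        tangent = cur - prev
        norm = np.linalg.norm(tangent)
        if norm == 0:
            break
        tangent = tangent / norm
        probe = cur + step * tangent
        centroid = _slab_centroid(blade, probe, tangent, h, radius,
                                  min_points)
        ok = centroid is not None and \
            np.linalg.norm(centroid - probe) <= 1.25 * step
        if ok and float((centroid - cur) @ tangent) < 0.25 * step:
            break  # plane stopped advancing: reached the tip
        if ok:
            nodes.extend(pending)
            pending = []
            nodes.append(centroid)
            blind = 0
        else:
            blind += 1
            if blind > max_blind:
                break
            pending.append(probe)
    return nodes


def _tilted_arc_angle(
    x: np.ndarray,
    y: np.ndarray,
    x_lo: float = 0.02,
    x_hi: float = 0.28,
) -> float | None:
    """Base-tangent angle from a tilted-parabola fit of the blade arc.

    A smooth arching vein is well modeled by a conic arc whose axis need
    not be vertical; the rotation angle is optimized against orthogonal
    residuals and the tangent is evaluated where the arc meets the stem
    line (x = 0). Returns the angle from the stem axis in degrees, or
    None when the fit is not usable.
    """
    from scipy.optimize import minimize_scalar

    m = (x > x_lo) & (x < x_hi)
    if m.sum() < 40:
        return None
    xs, ys = x[m], y[m]
    pts = np.stack([xs, ys], axis=1)

    def fit_at(phi):
        c, s = np.cos(phi), np.sin(phi)
        xp = c * xs + s * ys
        yp = -s * xs + c * ys
        co = np.polyfit(xp, yp, 2)
        tt = np.linspace(xp.min() - 0.03, xp.max() + 0.03, 250)
        rot = np.array([[c, -s], [s, c]])
        curve = np.stack([tt, np.polyval(co, tt)], axis=1) @ rot.T
        dist, _ = cKDTree(curve).query(pts)
        return float((dist**2).sum()), co

    res = minimize_scalar(lambda p: fit_at(p)[0],
                          bounds=(np.radians(-15.0), np.radians(75.0)),
                          method="bounded", options={"xatol": 1e-3})
    phi = float(res.x)
    _, co = fit_at(phi)
    c, s = np.cos(phi), np.sin(phi)
    a2, a1, a0 = co
    # x(t) = c t - s (a0 + a1 t + a2 t^2) = 0 at the stem line
    A, B, C = -s * a2, c - s * a1, -s * a0
    if abs(A) < 1e-12:
        roots = [-C / B] if abs(B) > 1e-12 else []
    else:
        disc = B * B - 4 * A * C
        if disc < 0:
            return None
        r = np.sqrt(disc)
        roots = [(-B + r) / (2 * A), (-B - r) / (2 * A)]
    if not roots:
        return None
    t_inner = c * xs.min() + s * ys[np.argmin(xs)]
    t0 = min(roots, key=lambda rr: abs(rr - t_inner))
    dp = 2 * a2 * t0 + a1
    dx = c - s * dp
    dy = s + c * dp
    if dx < 0:
        dx, dy = -dx, -dy
    return float(np.degrees(np.arctan2(dx, dy)))


def _components(points: np.ndarray, radius: float) -> np.ndarray:
    """Connected-component labels of a point set at linking ``radius``."""
    from scipy import sparse
    from scipy.sparse.csgraph import connected_components

    tree = cKDTree(points)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = len(points)
    adj = sparse.coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                            shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def calibrate_skeleton(
    skeleton: PlantSkeleton,
    organ_clouds: dict[int, np.ndarray],
    stem_cloud: np.ndarray | None = None,
    config: CalibrationConfig | None = None,
) -> PlantSkeleton:
    """Full calibration: stem straightening + per-leaf vein correction.

    ``organ_clouds`` maps leaf index -> original points attributed to that
    leaf. Leaf count and stem/leaf assignment never change.
    """
    cfg = config or CalibrationConfig()
    out = calibrate_stem(skeleton, stem_cloud, cfg)
    parts = [np.asarray(c) for c in organ_clouds.values() if len(c)]
    if stem_cloud is not None and len(np.atleast_2d(stem_cloud)):
        parts.append(np.asarray(stem_cloud))
    full_cloud = np.vstack(parts) if parts else np.empty((0, 3))
    for i, leaf in enumerate(out.leaves):
        cloud = organ_clouds.get(i)
        if cloud is None or len(cloud) == 0:
            log.warning("leaf %d has no attributed points; left uncalibrated", i)
            continue
        calibrated = calibrate_leaf(leaf, cloud, cfg)
        if cfg.refine_bases:
            junction = np.empty((0, 3))
            if stem_cloud is not None and len(stem_cloud):
                # only the stem points of *this* junction's neighborhood:
                # corridors of other leaves would contaminate the base fit
                sc = np.asarray(stem_cloud)
                near = np.linalg.norm(
                    sc - out.stem[out.growth_index[i]], axis=1) < 0.18
                junction = sc[near]
            calibrated, tangent = _refine_leaf_base(
                calibrated, np.asarray(cloud), junction, full_cloud,
                out.stem, out.growth_index[i], cfg)
            out.base_tangents[i] = tangent
        out.leaves[i] = calibrated
        out.leaf_ids[i] = np.full(len(calibrated), -1, dtype=int)
        out.leaf_ids[i][0] = skeleton.leaf_ids[i][0]
    return out
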