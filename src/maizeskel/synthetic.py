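"""Procedural maize plants with exact ground-truth skeletons.

A generated plant is a near-vertical stem cylinder plus 5–15 leaves
attached at strictly increasing heights with alternate (~180°)
phyllotaxy. Each leaf vein is a quadratic Bézier arc in the vertical
plane of its azimuth — rising at the insertion angle, arching over an
apex, then drooping toward the tip — with a ribbon of surface points of
tapering width sampled around it. Sensor noise is isotropic Gaussian;
optional extras emulate the scanning scene: a brown pot shell under the
plant and sparse outlier clutter.

Colors follow a shading model: each point's RGB is its organ's base color
scaled by a random brightness factor (matte surfaces under varying
illumination) plus small independent per-channel sensor noise. Brightness
scaling leaves the pot color filter's difference measure at zero, which is
exactly the property the filter relies on.

Ground truth carries the analytic stem axis and vein curves (finely
sampled), per-point organ labels, and the trait table evaluated directly
on the analytic curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cloud import ColoredPointCloud
from .traits import TraitTable

__all__ = ["PlantSpec", "GroundTruth", "make_plant", "make_study"]

LABEL_STEM = 0
LABEL_POT = -1
LABEL_OUTLIER = -2
# leaf i (1-based rank by insertion height) gets label i

LEAF_RGB = np.array([40.0, 150.0, 40.0])
STEM_RGB = np.array([60.0, 160.0, 55.0])
POT_RGB = np.array([140.0, 70.0, 40.0])
FINE_SAMPLES = 600


@dataclass
class PlantSpec:
    """Complete parameterization of one synthetic plant."""

    seed: int = 0
    n_leaves: int = 8
    stem_height: float = 1.6  # m
    stem_radius: float = 0.012  # m
    stem_tilt_deg: float = 0.0
    stem_tilt_azimuth_deg: float = 0.0
    insertion_fracs: np.ndarray = None  # of stem height, strictly increasing
    insertion_angles_deg: np.ndarray = None  # from the stem axis
    azimuths_deg: np.ndarray = None
    vein_lengths: np.ndarray = None  # arc length, m
    tip_x_fracs: np.ndarray = None  # tip offset along the leaf plane, of scale
    tip_z_fracs: np.ndarray = None  # tip height offset (droop), of scale
    leaf_width_max: float = 0.07  # m
    noise_sigma: float = 0.001  # m
    points_per_plant: int = 10000
    pot: bool = False
    pot_rgb: tuple = (140, 70, 40)
    pot_radius: float = 0.12
    pot_height: float = 0.15
    outlier_fraction: float = 0.0

    def __post_init__(self) -> None:
        n = self.n_leaves
        if not 1 <= n <= 20:
            raise ValueError("n_leaves out of range")
        rng = np.random.default_rng(self.seed)
        if self.insertion_fracs is None:
            base = np.linspace(0.18, 0.85, n)
            gap = (0.85 - 0.18) / max(n - 1, 1)
            self.insertion_fracs = base + rng.uniform(-0.3, 0.3, n) * gap
        self.insertion_fracs = np.asarray(self.insertion_fracs, float)
        if np.any(np.diff(self.insertion_fracs) <= 0):
            raise ValueError("insertion heights must be strictly increasing")
        if self.insertion_angles_deg is None:
            self.insertion_angles_deg = rng.uniform(25.0, 50.0, n)
        if self.azimuths_deg is None:
            first = rng.uniform(0.0, 360.0)
            steps = 180.0 + rng.uniform(-10.0, 10.0, n - 1) if n > 1 else []
            self.azimuths_deg = np.mod(first + np.concatenate([[0.0],
                                       np.cumsum(steps)]), 360.0)
        if self.vein_lengths is None:
            self.vein_lengths = self.stem_height * rng.uniform(0.35, 0.55, n)
        if self.tip_x_fracs is None:
            self.tip_x_fracs = rng.uniform(0.70, 0.90, n)
        if self.tip_z_fracs is None:
            self.tip_z_fracs = rng.uniform(-0.30, 0.10, n)
        for name in ("insertion_angles_deg", "azimuths_deg", "vein_lengths",
                     "tip_x_fracs", "tip_z_fracs"):
            setattr(self, name, np.asarray(getattr(self, name), float))
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per leaf")
        if np.any(self.vein_lengths <= 0) or self.stem_height <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class GroundTruth:
    """Analytic skeleton + labels + trait table of one synthetic plant."""

    spec: PlantSpec
    stem_polyline: np.ndarray
    veins: list  # fine (FINE_SAMPLES, 3) polylines, base -> tip
    traits: TraitTable
    labels: np.ndarray = field(repr=False, default=None)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _stem_axis(spec: PlantSpec) -> np.ndarray:
    t = np.radians(spec.stem_tilt_deg)
    a = np.radians(spec.stem_tilt_azimuth_deg)
    return np.array([np.sin(t) * np.cos(a), np.sin(t) * np.sin(a), np.cos(t)])


def _leaf_frame(axis: np.ndarray, azimuth_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """(outward horizontal-ish in-plane unit u, plane normal m)."""
    phi = np.radians(azimuth_deg)
    u0 = np.array([np.cos(phi), np.sin(phi), 0.0])
    u = _unit(u0 - (u0 @ axis) * axis)
    m = _unit(np.cross(u, axis))
    return u, m


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
            t: np.ndarray) -> np.ndarray:
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _leaf_curve(spec: PlantSpec, i: int, axis: np.ndarray) -> dict:
    """Analytic vein of leaf ``i``: control points scaled to the target
    arc length, plus fine samples and cumulative arc."""
    attach = spec.insertion_fracs[i] * spec.stem_height * axis
    u, m = _leaf_frame(axis, spec.azimuths_deg[i])
    theta = np.radians(spec.insertion_angles_deg[i])
    d0 = np.sin(theta) * u + np.cos(theta) * axis
    # unit-scale control net, then rescale so the arc length matches
    c1 = 0.45
    p1 = c1 * d0
    p2 = spec.tip_x_fracs[i] * u + spec.tip_z_fracs[i] * axis
    t = np.linspace(0.0, 1.0, FINE_SAMPLES)
    fine = _bezier(np.zeros(3), p1, p2, t)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(fine, axis=0),
                                                          axis=1))])
    scale = spec.vein_lengths[i] / arc[-1]
    p1, p2, fine, arc = p1 * scale, p2 * scale, fine * scale, arc * scale
    fine = fine + attach
    return {"attach": attach, "p1": attach + p1, "p2": attach + p2,
            "fine": fine, "arc": arc, "normal": m, "tangent0": d0}


def _truth_traits(spec: PlantSpec, axis: np.ndarray, curves: list,
                  plant_id: str) -> TraitTable:
    rows = []
    ref_dir = None
    for i, c in enumerate(curves):
        tip_vec = c["fine"][-1] - c["fine"][0]
        az_abs = np.degrees(np.arctan2(tip_vec[1], tip_vec[0]))
        if i == 0:
            ref_dir = az_abs
        apex = int(np.argmax(c["fine"][:, 2]))
        rows.append({
            "plant_id": plant_id,
            "leaf_rank": i + 1,
            "leaf_length_m": float(c["arc"][-1]),
            "inclination_deg": float(spec.insertion_angles_deg[i]),
            "top_length_m": float(c["arc"][apex]),
            "azimuth_deg": float(np.mod(az_abs - ref_dir, 360.0)),
            "growth_height_m": float(c["attach"][2]),
        })
    top = spec.stem_height * axis[2]
    height = max([top] + [float(c["fine"][:, 2].max()) for c in curves])
    return TraitTable(pd.DataFrame(rows), height, plant_id)


def _width_profile(t: np.ndarray, w_max: float) -> np.ndarray:
    """Trapezoidal blade width: quick flare from the base, taper to the tip."""
    return w_max * np.minimum(np.clip(t / 0.15, 0, 1),
                              np.clip((1 - t) / 0.2, 0, 1) ** 0.8)


def _shade(base_rgb: np.ndarray, n: int, rng: np.random.Generator,
           brightness_amp: float, channel_sigma: float = 0.6) -> np.ndarray:
    """Brightness-scaled base color + per-channel sensor noise."""
    scale = 1.0 + rng.uniform(-brightness_amp, brightness_amp, (n, 1)) / base_rgb.max()
    rgb = base_rgb * scale + rng.normal(0.0, channel_sigma, (n, 3))
    return np.clip(rgb, 1.0, 255.0)


def make_plant(spec: PlantSpec) -> tuple[ColoredPointCloud, GroundTruth]:
    """Sample one plant's colored cloud and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    axis = _stem_axis(spec)
    curves = [_leaf_curve(spec, i, axis) for i in range(spec.n_leaves)]
    # point budget proportional to surface area
    stem_area = 2 * np.pi * spec.stem_radius * spec.stem_height
    leaf_areas = np.array([0.7 * spec.leaf_width_max * c["arc"][-1]
                           for c in curves])
    n_total = spec.points_per_plant
    n_out = int(round(spec.outlier_fraction * n_total))
    n_pot = int(round(0.10 * n_total)) if spec.pot else 0
    n_plant = n_total - n_out - n_pot
    areas = np.concatenate([[stem_area], leaf_areas])
    counts = np.maximum((n_plant * areas / areas.sum()).astype(int), 30)

    positions, colors, labels = [], [], []
    # stem cylinder
    ns = counts[0]
    tt = rng.uniform(0, 1, ns)
    psi = rng.uniform(0, 2 * np.pi, ns)
    e1, e2 = _leaf_frame(axis, 0.0)
    radial = (np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * np.cross(axis, e1))
    pts = tt[:, None] * spec.stem_height * axis + spec.stem_radius * radial
    positions.append(pts)
    colors.append(_shade(STEM_RGB, ns, rng, 10.0))
    labels.append(np.full(ns, LABEL_STEM))
    # leaf ribbons
    for i, c in enumerate(curves):
        nl = counts[i + 1]
        s = rng.uniform(0, c["arc"][-1], nl)
        t = np.interp(s, c["arc"], np.linspace(0, 1, FINE_SAMPLES))
        on_vein = _bezier(c["attach"], c["p1"], c["p2"], t)
        w = _width_profile(t, spec.leaf_width_max)
        eta = rng.uniform(-1, 1, nl)
        lateral = (eta * w / 2)[:, None] * c["normal"]
        sag = (0.15 * w * eta**2)[:, None] * np.array([0.0, 0.0, 1.0])
        positions.append(on_vein + lateral - sag)
        colors.append(_shade(LEAF_RGB, nl, rng, 10.0))
        labels.append(np.full(nl, i + 1))
    # pot shell
    if n_pot:
        psi = rng.uniform(0, 2 * np.pi, n_pot)
        z = rng.uniform(-spec.pot_height, -0.005, n_pot)
        pts = np.stack([spec.pot_radius * np.cos(psi),
                        spec.pot_radius * np.sin(psi), z], axis=1)
        positions.append(pts)
        colors.append(_shade(np.asarray(spec.pot_rgb, float), n_pot, rng, 5.0))
        labels.append(np.full(n_pot, LABEL_POT))
    pos = np.vstack(positions)
    if spec.noise_sigma > 0:
        pos += rng.normal(0.0, spec.noise_sigma, pos.shape)
    # sparse outlier clutter, kept away from real surfaces
    if n_out:
        tree = cKDTree(pos)
        lo, hi = pos.min(axis=0), pos.max(axis=0)
        span = hi - lo
        placed = []
        while len(placed) < n_out:
            center = lo - 0.1 * span + rng.uniform(0, 1, 3) * 1.2 * span
            if tree.query(center)[0] < 0.10:
                continue
            size = int(rng.integers(1, 5))
            placed.extend(center + rng.normal(0, 0.01, (size, 3)))
        placed = np.asarray(placed[:n_out])
        pos = np.vstack([pos, placed])
        colors.append(rng.uniform(60, 200, (n_out, 3)))
        labels.append(np.full(n_out, LABEL_OUTLIER))
    cloud = ColoredPointCloud(pos, np.vstack(colors).astype(np.uint8),
                              np.concatenate(labels))
    stem_poly = np.linspace(0, 1, 200)[:, None] * spec.stem_height * axis
    plant_id = f"plant{spec.seed}"
    truth = GroundTruth(
        spec=spec,
        stem_polyline=stem_poly,
        veins=[c["fine"] for c in curves],
        traits=_truth_traits(spec, axis, curves, plant_id),
        labels=cloud.labels,
    )
    return cloud, truth


def make_study(
    n_plants: int,
    seed: int = 0,
    difficulty: str = "realistic",
    points_per_plant: int = 10000,
) -> list[tuple[ColoredPointCloud, GroundTruth]]:
    """A seeded multi-plant study emulating a scanning campaign.

    ``easy`` plants have sigma = 1 mm sensor noise and no scene clutter;
    ``realistic`` plants add sigma = 4 mm noise, a pot and 1 % outliers.
    """
    if difficulty not in ("easy", "realistic"):
        raise ValueError("difficulty must be 'easy' or 'realistic'")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_plants):
        child = int(rng.integers(0, 2**31 - 1))
        crng = np.random.default_rng(child)
        spec = PlantSpec(
            seed=child,
            n_leaves=int(crng.integers(8, 13)),
            stem_height=float(crng.uniform(1.1, 2.0)),
            stem_tilt_deg=float(crng.uniform(0.0, 2.0)),
            stem_tilt_azimuth_deg=float(crng.uniform(0.0, 360.0)),
            leaf_width_max=float(crng.uniform(0.06, 0.09)),
            noise_sigma=0.001 if difficulty == "easy" else 0.004,
            points_per_plant=points_per_plant,
            pot=difficulty == "realistic",
            outlier_fraction=0.0 if difficulty == "easy" else 0.01,
        )
        out.append(make_plant(spec))
    return out
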