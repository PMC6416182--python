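import numpy as np
import pytest

from maizeskel.calibration import (
    CalibrationConfig,
    _despike_polyline,
    calibrate_leaf,
    calibrate_stem,
    fit_line,
)
from maizeskel.topology import PlantSkeleton


def ribbon_cloud(vein, width=0.05, n=3000, sigma=0.002, seed=0):
    """Surface points around a parametric vein polyline."""
    rng = np.random.default_rng(seed)
    seg = np.linalg.norm(np.diff(vein, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s = rng.uniform(0, arc[-1], n)
    t = np.array([np.interp(s, arc, vein[:, d]) for d in range(3)]).T
    tangents = np.gradient(vein, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    ti = np.array([np.interp(s, arc, tangents[:, d]) for d in range(3)]).T
    lateral = np.cross(ti, [0, 0, 1.0])
    lateral /= np.maximum(np.linalg.norm(lateral, axis=1, keepdims=True), 1e-9)
    offs = rng.uniform(-width / 2, width / 2, n)[:, None]
    return t + offs * lateral + rng.normal(0, sigma, (n, 3))


def quarter_arc_vein(n=200, r=0.5):
    th = np.linspace(0, np.pi / 2, n)
    return np.stack([r * np.sin(th), np.zeros(n), r * (1 - np.cos(th))], 1)


class TestFitLine:
    def test_exact_line(self):
        t = np.linspace(0, 1, 20)
        pts = np.outer(t, [1.0, 2.0, 2.0])
        origin, d = fit_line(pts)
        assert abs(abs(d @ np.array([1, 2, 2.0]) / 3.0) - 1) < 1e-12

    def test_noisy_line_direction(self, rng):
        t = rng.uniform(0, 1, 100)
        pts = np.outer(t, [0, 0, 1.0]) + rng.normal(0, 0.01, (100, 3))
        _, d = fit_line(pts)
        assert abs(d[2]) > 0.999


class TestCalibrateLeaf:
    def test_displaced_nodes_recover_vein(self):
        vein = quarter_arc_vein()
        cloud = ribbon_cloud(vein, sigma=0.001)
        # skeleton nodes: vein samples displaced laterally by 1 cm
        idx = np.linspace(0, len(vein) - 1, 12).astype(int)
        nodes = vein[idx] + np.array([0, 0.01, 0])
        out = calibrate_leaf(nodes, cloud)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(vein).query(out[1:])
        assert np.median(d) < 0.004

    def test_near_fixed_point_when_on_vein(self):
        vein = quarter_arc_vein()
        cloud = ribbon_cloud(vein, sigma=0.001)
        idx = np.linspace(0, len(vein) - 1, 12).astype(int)
        nodes = vein[idx]
        out = calibrate_leaf(nodes, cloud)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(vein).query(out)
        assert np.median(d) < 0.003

    def test_tip_extension_recovers_missing_end(self):
        vein = quarter_arc_vein()
        cloud = ribbon_cloud(vein, sigma=0.001)
        # skeleton stops 25% short of the tip
        idx = np.linspace(0, int(0.75 * (len(vein) - 1)), 10).astype(int)
        out = calibrate_leaf(vein[idx], cloud)
        tip_gap = np.linalg.norm(out[-1] - vein[-1])
        spacing = np.linalg.norm(np.diff(out, axis=0), axis=1).mean()
        assert tip_gap < 3 * spacing

    def test_empty_cloud_returns_unchanged(self):
        nodes = quarter_arc_vein(10)
        out = calibrate_leaf(nodes, np.empty((0, 3)))
        np.testing.assert_array_equal(out, nodes)


class TestDespike:
    def test_reversal_removed(self):
        poly = np.array([[0, 0, 0], [1, 0, 0], [0.5, 0, 0.01],
                         [1.5, 0, 0.02], [2.5, 0, 0.02]], float)
        out = _despike_polyline(poly)
        seg = np.diff(out, axis=0)
        # no segment reverses direction along x after despiking
        assert (seg[:, 0] > 0).all()

    def test_smooth_arc_untouched(self):
        vein = quarter_arc_vein(30)
        out = _despike_polyline(vein)
        assert len(out) == len(vein)


def vertical_stem_skeleton(bend=0.0):
    z = np.linspace(0, 1.0, 21)
    stem = np.stack([np.zeros_like(z), np.zeros_like(z), z], 1)
    if bend:
        stem[9:12, 0] += bend  # lateral kink near a growth point
    leaves = [np.array([[0.0, 0.0, 0.5], [0.1, 0.0, 0.55], [0.2, 0, 0.57]])]
    return PlantSkeleton(stem=stem, leaves=leaves, growth_index=[10])


class TestCalibrateStem:
    def test_straight_stem_fixed_point(self):
        skel = vertical_stem_skeleton()
        out = calibrate_stem(skel, config=CalibrationConfig(
            extend_stem_ends=False))
        np.testing.assert_allclose(out.stem, skel.stem, atol=1e-9)

    def test_bent_nodes_projected_collinear(self):
        skel = vertical_stem_skeleton(bend=0.02)
        out = calibrate_stem(skel, config=CalibrationConfig(
            extend_stem_ends=False))
        # each section's owned nodes are exactly collinear
        for a, b in [(0, 10), (10, 21)]:
            sec = out.stem[a:b]
            if len(sec) < 3:
                continue
            c = sec.mean(axis=0)
            _, sv, _ = np.linalg.svd(sec - c, full_matrices=False)
            assert sv[1] < 1e-10 * max(sv[0], 1)

    def test_stem_cloud_robust_to_junction_bend(self, rng):
        skel = vertical_stem_skeleton(bend=0.03)
        # cylindrical stem surface cloud around the true (straight) axis
        z = rng.uniform(0, 1, 3000)
        phi = rng.uniform(0, 2 * np.pi, 3000)
        cloud = np.stack([0.012 * np.cos(phi), 0.012 * np.sin(phi), z], 1)
        out = calibrate_stem(skel, cloud, CalibrationConfig(
            extend_stem_ends=False))
        lateral = np.linalg.norm(out.stem[:, :2], axis=1)
        assert lateral.max() < 0.005

    def test_end_extension_reaches_cloud_extremes(self, rng):
        skel = vertical_stem_skeleton()
        # stem surface extends beyond both skeleton ends
        z = rng.uniform(-0.15, 1.15, 4000)
        phi = rng.uniform(0, 2 * np.pi, 4000)
        cloud = np.stack([0.012 * np.cos(phi), 0.012 * np.sin(phi), z], 1)
        out = calibrate_stem(skel, cloud, CalibrationConfig())
        assert out.stem[0][2] < -0.05
        assert out.stem[-1][2] > 1.05
        # growth index still points at the same physical node
        g = out.growth_index[0]
        assert abs(out.stem[g][2] - 0.5) < 0.03

    def test_leaf_count_preserved(self):
        skel = vertical_stem_skeleton(bend=0.02)
        out = calibrate_stem(skel)
        assert out.n_leaves == skel.n_leaves
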