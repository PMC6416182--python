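import numpy as np
import pytest

from maizeskel.cloud import ColoredPointCloud
from maizeskel.denoise import (
    color_difference,
    denoise_plant,
    density_threshold,
    drop_small_clusters,
    near_propagation_cluster,
    remove_pot,
)
from maizeskel.synthetic import LABEL_OUTLIER, LABEL_POT


class TestColorDifference:
    def test_identical_colors_zero(self):
        assert color_difference((120, 80, 40), (120, 80, 40)) == 0.0

    def test_grays_always_match(self):
        # both chroma vectors vanish -> angle convention 0 -> D = 0 even
        # though the brightnesses differ
        assert color_difference((100, 100, 100), (200, 200, 200)) == 0.0

    def test_equal_brightness_hue_flip_is_invisible(self):
        # red vs green have equal channel means, so the brightness-ratio
        # factor is zero and D = 0 despite opposite hues
        assert color_difference((255, 0, 0), (0, 255, 0)) == pytest.approx(0.0)

    def test_brightness_scaling_invariance(self):
        base = np.array([140.0, 70.0, 40.0])
        d = color_difference(base, 1.3 * base)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_different_colors_positive(self):
        assert color_difference((140, 70, 40), (40, 150, 40)) > 1.0

    def test_black_rejected(self):
        with pytest.raises(ValueError):
            color_difference((0, 0, 0), (10, 10, 10))


class TestRemovePot:
    def test_exact_match_all_removed(self, rng):
        col = np.tile([140, 70, 40], (50, 1))
        cloud = ColoredPointCloud(rng.random((50, 3)), col)
        plant, pot = remove_pot(cloud, [[140, 70, 40]])
        assert plant is None and pot.n == 50

    def test_distant_colors_kept(self, rng):
        cloud = ColoredPointCloud(rng.random((50, 3)),
                                  np.tile([40, 150, 40], (50, 1)))
        plant, pot = remove_pot(cloud, [[140, 70, 40]])
        assert pot is None and plant.n == 50

    def test_conserves_points(self, realistic_plant):
        cloud, _ = realistic_plant
        samples = cloud.colors[cloud.labels == LABEL_POT][:5].astype(float)
        plant, pot = remove_pot(cloud, samples)
        assert plant.n + pot.n == cloud.n

    def test_synthetic_scene_separation(self, realistic_plant):
        """>=99% of pot points removed, <=1% of plant points lost."""
        from maizeskel.pipeline import sample_pot_colors
        cloud, _ = realistic_plant
        pot_idx = np.nonzero(cloud.labels == LABEL_POT)[0]
        samples = sample_pot_colors(cloud, n_samples=5)
        plant, pot = remove_pot(cloud, samples)
        removed_true_pot = np.sum(pot.labels == LABEL_POT)
        assert removed_true_pot / len(pot_idx) >= 0.99
        plant_total = np.sum(cloud.labels > LABEL_POT + 1)  # stem + leaves
        lost_plant = np.sum(pot.labels >= 0)
        assert lost_plant / plant_total <= 0.01

    def test_empty_noise_list_rejected(self, small_cloud):
        with pytest.raises(ValueError):
            remove_pot(small_cloud, np.empty((0, 3)))


class TestClustering:
    def test_two_blobs(self, rng):
        blob = rng.normal(0, 0.01, (30, 3))
        pos = np.vstack([blob, blob + [1.0, 0, 0]])
        cloud = ColoredPointCloud(pos, np.zeros((60, 3)))
        cs = near_propagation_cluster(cloud, 0.1)
        assert len(cs) == 2
        assert sorted(cs.sizes.tolist()) == [30, 30]
        assert len(near_propagation_cluster(cloud, 2.0)) == 1

    def test_matches_brute_force_union_find(self, rng):
        pos = rng.random((200, 3))
        cloud = ColoredPointCloud(pos, np.zeros((200, 3)))
        r = 0.12
        cs = near_propagation_cluster(cloud, r)
        # O(n^2) union-find oracle
        parent = list(range(200))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(200):
            for j in range(i + 1, 200):
                if np.linalg.norm(pos[i] - pos[j]) <= r:
                    parent[find(i)] = find(j)
        oracle = {}
        for i in range(200):
            oracle.setdefault(find(i), set()).add(i)
        ours = {frozenset(c.tolist()) for c in cs.clusters}
        assert ours == {frozenset(s) for s in oracle.values()}

    def test_partition_covers_all_points(self, small_cloud):
        cs = near_propagation_cluster(small_cloud, 0.2)
        joined = np.sort(np.concatenate(cs.clusters))
        np.testing.assert_array_equal(joined, np.arange(small_cloud.n))


class TestDropSmallClusters:
    def _fixture(self, rng):
        # compact ball-shaped "plant" (no stray tail points of its own)
        v = rng.normal(size=(1500, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        plant = v * 0.15 * rng.uniform(0, 1, (1500, 1)) ** (1 / 3)
        noise = [rng.normal(0, 0.002, (3, 3)) + [c, c, 2.0]
                 for c in np.linspace(1, 3, 12)]
        pos = np.vstack([plant] + noise)
        return ColoredPointCloud(pos, np.zeros((len(pos), 3)))

    def test_noise_clusters_removed(self, rng):
        cloud = self._fixture(rng)
        r = 0.05
        cs = near_propagation_cluster(cloud, r)
        assert len(cs) == 13
        out = drop_small_clusters(cs, cloud, r, num=10, seed=0)
        assert out.n == 1500

    def test_threshold_formula(self, rng):
        cloud = self._fixture(rng)
        r = 0.06
        thr = density_threshold(cloud, r, num=cloud.n, seed=0)
        # oracle: exact mean neighborhood count over every point
        from scipy.spatial import cKDTree
        tree = cKDTree(cloud.positions)
        counts = [len(tree.query_ball_point(p, r)) for p in cloud.positions]
        assert thr == pytest.approx(0.5 * np.mean(counts))

    def test_sampled_vs_exact_same_decision(self, rng):
        cloud = self._fixture(rng)
        r = 0.05
        cs = near_propagation_cluster(cloud, r)
        out10 = drop_small_clusters(cs, cloud, r, num=10, seed=0)
        out_all = drop_small_clusters(cs, cloud, r, num=cloud.n, seed=0)
        assert out10.n == out_all.n

    def test_single_cluster_survives(self, rng):
        pos = rng.normal(0, 0.05, (300, 3))
        cloud = ColoredPointCloud(pos, np.zeros((300, 3)))
        cs = near_propagation_cluster(cloud, 0.05)
        out = drop_small_clusters(cs, cloud, 0.05)
        assert out.n > 0


def test_denoise_pipeline_removes_scene_clutter(realistic_plant):
    cloud, _ = realistic_plant
    rng = np.random.default_rng(1)
    pot_idx = np.nonzero(cloud.labels == LABEL_POT)[0]
    samples = cloud.colors[rng.choice(pot_idx, 5, replace=False)].astype(float)
    clean = denoise_plant(cloud, samples, seed=0)
    assert np.all(clean.labels != LABEL_POT)
    assert np.all(clean.labels != LABEL_OUTLIER)
    plant_total = np.sum(cloud.labels >= 0)
    assert clean.n >= 0.97 * plant_total


def test_denoise_deterministic(realistic_plant):
    cloud, _ = realistic_plant
    samples = cloud.colors[cloud.labels == LABEL_POT][:5].astype(float)
    a = denoise_plant(cloud, samples, seed=3)
    b = denoise_plant(cloud, samples, seed=3)
    np.testing.assert_array_equal(a.positions, b.positions)
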