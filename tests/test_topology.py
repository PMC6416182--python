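import networkx as nx
import numpy as np
import pytest

from maizeskel.topology import (
    SkeletonGraph,
    break_loops,
    connect_knn,
    ensure_connected,
    plane_fit,
    segment_stem_leaves,
)


class TestConnectKnn:
    def test_two_points_one_edge(self):
        g = connect_knn(np.array([[0, 0, 0], [1, 0, 0.0]]))
        assert g.edges == [(0, 1)]

    def test_square_forms_cycle(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]])
        g = connect_knn(pts, k=3)
        gx = g.to_networkx()
        # the four sides are admitted before the (longer) diagonals; with
        # a degree budget of 3 each diagonal may also fit, but the 4-cycle
        # of sides must be present
        for e in [(0, 1), (1, 2), (2, 3), (0, 3)]:
            assert gx.has_edge(*e)

    def test_chain_breaks_to_path(self):
        pts = np.zeros((10, 3))
        pts[:, 0] = np.arange(10)
        g = connect_knn(pts, k=3)
        tree = break_loops(ensure_connected(g))
        gx = tree.to_networkx()
        assert nx.is_tree(gx)
        # after loop breaking, consecutive chain edges remain
        for i in range(9):
            assert gx.has_edge(i, i + 1)

    def test_degree_cap(self, rng):
        g = connect_knn(rng.random((100, 3)), k=3)
        assert g.degrees.max() <= 3


class TestPlaneFit:
    def test_coplanar_zero_residual(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        coeffs, e = plane_fit(pts)
        assert e == pytest.approx(0, abs=1e-20)
        np.testing.assert_allclose(np.abs(coeffs[:3]), [0, 0, 1], atol=1e-12)

    def test_symmetric_tetrahedron(self):
        pts = np.array([[1, 0, 0.3], [-1, 0, -0.3], [0, 1, 0.3],
                        [0, -1, -0.3]])
        coeffs, _ = plane_fit(pts)
        # fitted plane passes through the centroid (origin)
        assert coeffs[3] == pytest.approx(0, abs=1e-12)

    def test_noisy_plane_normal(self, rng):
        n = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        u = np.array([1.0, -1.0, 0]) / np.sqrt(2)
        v = np.cross(n, u)
        ab = rng.uniform(-1, 1, (20, 2))
        pts = np.outer(ab[:, 0], u) + np.outer(ab[:, 1], v) \
            + rng.normal(0, 0.01, (20, 1)) * n + n / np.sqrt(3)
        coeffs, _ = plane_fit(pts)
        cos = abs(float(coeffs[:3] @ n))
        assert np.degrees(np.arccos(min(cos, 1))) < 2.0

    def test_collinear_rejected(self):
        pts = np.outer(np.arange(5), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degenerate"):
            plane_fit(pts)


class TestBreakLoops:
    def test_tree_unchanged(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        g = SkeletonGraph(pts, [(0, 1), (1, 2)])
        out = break_loops(g)
        assert sorted(out.edges) == [(0, 1), (1, 2)]

    def test_triangle_lifted_vertex(self):
        """All W_s vanish on a triangle (its plane is exact), so the
        turning-angle term decides: the edge opposite the off-course
        vertex has the largest summed turning angles and is deleted."""
        pts = np.array([[0, 0, 0], [1, 0, 0.05], [2, 0, 0],
                        [3, 0, 0.0]])  # path context
        g = SkeletonGraph(pts, [(0, 1), (1, 2), (0, 2), (2, 3)])
        out = break_loops(g)
        gx = out.to_networkx()
        assert nx.is_tree(gx)
        # (0,2) shortcuts past the gently-bending vertex 1: its turning
        # angles against (0,1)/(1,2) are the largest -> deleted
        assert not gx.has_edge(0, 2)

    def test_square_appended_to_path(self):
        # planar square cycle; growth direction along +x path
        pts = np.array([
            [-2, 0, 0], [-1, 0, 0], [0, 0, 0],
            [1, 0.6, 0], [2, 0, 0], [1, -0.6, 0],
        ], dtype=float)
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (2, 5)]
        out = break_loops(SkeletonGraph(pts, edges))
        assert out.to_networkx().number_of_edges() == 5
        assert nx.is_tree(out.to_networkx())

    def test_random_graphs_yield_spanning_trees(self, rng):
        """100 random key-point sets: output is always a spanning tree and
        never disconnects."""
        for _ in range(100):
            P = rng.random((25, 3))
            g = ensure_connected(connect_knn(P, 3))
            tree = break_loops(g)
            gx = tree.to_networkx()
            assert nx.is_connected(gx)
            assert gx.number_of_edges() == len(P) - 1

    def test_disconnected_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [5, 0, 0], [6, 0, 0.0]])
        g = SkeletonGraph(pts, [(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="connected"):
            break_loops(g)


def make_plant_tree():
    """Hand-built tree: vertical stem of 8 nodes + one 3-node leaf at
    node 3, leaving at 45 degrees."""
    stem = np.stack([np.zeros(8), np.zeros(8), np.arange(8) * 0.1], axis=1)
    leaf = np.array([[0.07, 0, 0.37], [0.14, 0, 0.42], [0.21, 0, 0.44]])
    pts = np.vstack([stem, leaf])
    edges = [(i, i + 1) for i in range(7)] + [(3, 8), (8, 9), (9, 10)]
    return SkeletonGraph(pts, edges)


class TestSegmentation:
    def test_bare_chain_is_stem_only(self):
        pts = np.stack([np.zeros(6), np.zeros(6), np.arange(6) * 0.1], 1)
        g = SkeletonGraph(pts, [(i, i + 1) for i in range(5)])
        skel = segment_stem_leaves(g)
        assert skel.n_leaves == 0
        assert len(skel.stem) == 6
        assert skel.stem[0][2] == 0.0

    def test_single_leaf_plant(self):
        skel = segment_stem_leaves(make_plant_tree())
        assert skel.n_leaves == 1
        assert len(skel.stem) == 8  # stem passes the junction vertically
        leaf = skel.leaves[0]
        np.testing.assert_allclose(leaf[0], [0, 0, 0.3])  # growth point
        assert skel.growth_index[0] == 3

    def test_all_nodes_covered_once(self):
        skel = segment_stem_leaves(make_plant_tree())
        n_total = len(skel.stem) + sum(len(p) - 1 for p in skel.leaves)
        assert n_total == 11

    def test_synthetic_plant_segmentation(self, easy_plant):
        from maizeskel.cloud import bbox_diagonal
        from maizeskel.contraction import contract
        from maizeskel.sampling import adaptive_sample

        cloud, truth = easy_plant
        state = contract(cloud)
        diag = bbox_diagonal(cloud)
        keys = adaptive_sample(state, 0.015 * diag, 0.007 * diag)
        g = connect_knn(keys.positions, 3)
        g = ensure_connected(g, [state.positions[s]
                                 for s in keys.source_indices])
        skel = segment_stem_leaves(break_loops(g))
        # every true attachment has a growth point within a joint radius
        true_z = truth.traits.leaves.growth_height_m.values
        got_z = np.sort([skel.stem[i][2] for i in skel.growth_index])
        for tz in true_z:
            assert np.min(np.abs(got_z - tz)) < 0.12
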