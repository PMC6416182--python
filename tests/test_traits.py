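import numpy as np
import pandas as pd
import pytest

from maizeskel.topology import PlantSkeleton
from maizeskel.traits import (
    TraitTable,
    azimuth_angle,
    compute_traits,
    evaluate,
    growth_height,
    inclination_angle,
    leaf_length,
    plant_height,
    top_length,
)


def straight_leaf(direction, length=0.5, n=11, base=np.zeros(3)):
    t = np.linspace(0, length, n)[:, None]
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return base + t * d


class TestLeafLength:
    def test_two_nodes(self):
        assert leaf_length(np.array([[0, 0, 0], [0.5, 0, 0]])) == 0.5

    def test_quarter_circle_arc_limit(self):
        th = np.linspace(0, np.pi / 2, 101)
        poly = np.stack([np.cos(th), np.sin(th), np.zeros_like(th)], 1)
        assert leaf_length(poly) == pytest.approx(np.pi / 2, rel=1e-3)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            leaf_length(np.array([[0, 0, 0.0]]))


class TestTopLength:
    def test_straight_rising_leaf_equals_length(self):
        leaf = straight_leaf([1, 0, 1])
        assert top_length(leaf) == pytest.approx(leaf_length(leaf), rel=1e-6)

    def test_drooping_leaf_stops_at_apex(self):
        up = straight_leaf([1, 0, 1], length=0.3, n=7)
        down = straight_leaf([1, 0, -1], length=0.4, n=9, base=up[-1])
        leaf = np.vstack([up, down[1:]])
        assert top_length(leaf) == pytest.approx(0.3, abs=0.02)

    def test_never_exceeds_leaf_length(self, easy_plant):
        # property over synthetic ground-truth veins
        _, truth = easy_plant
        for vein in truth.veins:
            assert top_length(vein) <= leaf_length(vein) + 1e-9

    def test_apex_at_base_is_zero(self):
        leaf = straight_leaf([1, 0, -0.5])
        assert top_length(leaf) == 0.0


class TestAngles:
    def test_leaf_along_axis_zero_inclination(self):
        leaf = straight_leaf([0, 0, 1])
        assert inclination_angle(leaf, [0, 0, 1]) == pytest.approx(0.0)

    def test_horizontal_leaf_ninety(self):
        leaf = straight_leaf([1, 0, 0])
        assert inclination_angle(leaf, [0, 0, 1]) == pytest.approx(90.0)

    def test_azimuth_lowest_leaf_zero(self):
        leaf = straight_leaf([1, 0, 0.5])
        assert azimuth_angle(leaf, leaf) == 0.0

    def test_azimuth_opposite_leaf(self):
        a = straight_leaf([1, 0, 0.5])
        b = straight_leaf([-1, 0, 0.5])
        assert azimuth_angle(b, a) == pytest.approx(180.0)

    def test_azimuth_ccw_quadrant(self):
        ref = straight_leaf([1, 0, 0.5])
        leaf = straight_leaf([0, 1, 0.5])
        assert azimuth_angle(leaf, ref) == pytest.approx(90.0)

    def test_azimuth_prefers_measured_tangent(self):
        ref = straight_leaf([1, 0, 0.5])
        wandering = np.vstack([straight_leaf([0, 1, 0.5], length=0.3),
                               straight_leaf([-1, 0, 0], length=0.4,
                                             base=[0, 0.21, 0.21])[1:]])
        # growth-to-tip chord points backwards; the tangent says +y
        assert azimuth_angle(wandering, ref,
                             tangent=[0, 1, 0.7]) == pytest.approx(90.0)


def two_leaf_skeleton():
    z = np.linspace(0, 1.0, 11)
    stem = np.stack([np.zeros_like(z), np.zeros_like(z), z], 1)
    l1 = straight_leaf([1, 0, 1], base=[0, 0, 0.3])
    l2 = straight_leaf([-1, 0, 1], base=[0, 0, 0.6])
    return PlantSkeleton(stem=stem, leaves=[l2, l1], growth_index=[6, 3])


class TestPlantLevel:
    def test_growth_and_plant_height(self):
        skel = two_leaf_skeleton()
        tab = compute_traits(skel)
        assert tab.leaves.growth_height_m.tolist() == pytest.approx([0.3, 0.6])
        # apex: stem top at 1.0, upper leaf rises to 0.6 + 0.5/sqrt(2)
        assert tab.plant_height_m == pytest.approx(1.0, abs=1e-9)

    def test_plant_height_invariant_under_rigid_motion(self):
        skel = two_leaf_skeleton()
        h0 = plant_height(skel)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        shift = np.array([3.0, -2.0, 0.0])
        moved = PlantSkeleton(
            stem=skel.stem @ R.T + shift,
            leaves=[lf @ R.T + shift for lf in skel.leaves],
            growth_index=list(skel.growth_index))
        assert plant_height(moved) == pytest.approx(h0, abs=1e-12)

    def test_ranks_sorted_by_height(self):
        tab = compute_traits(two_leaf_skeleton())
        assert tab.leaves.leaf_rank.tolist() == [1, 2]
        assert tab.leaves.growth_height_m.is_monotonic_increasing


def make_table(values, height, pid="p"):
    df = pd.DataFrame({
        "plant_id": pid,
        "leaf_rank": np.arange(1, len(values) + 1),
        "leaf_length_m": values,
        "inclination_deg": 10 * np.asarray(values),
        "top_length_m": 0.5 * np.asarray(values),
        "azimuth_deg": np.linspace(0, 300, len(values)),
        "growth_height_m": np.linspace(0.2, 1.2, len(values)),
    })
    return TraitTable(df, height, pid)


class TestEvaluate:
    def test_perfect_prediction(self):
        t = make_table([0.5, 0.6, 0.7, 0.8], 2.0)
        rep = evaluate(t, t)
        assert (rep.nrmse_pct.round(12) == 0).all()
        assert (rep.r2.dropna() == 1).all()

    def test_constant_offset_nrmse(self):
        truth = make_table([0.5, 0.6, 0.7, 0.8], 2.0)
        mean = np.mean([0.5, 0.6, 0.7, 0.8])
        pred = make_table(np.array([0.5, 0.6, 0.7, 0.8]) + 0.1 * mean, 2.0)
        rep = evaluate(pred, truth)
        assert rep.loc["leaf_length_m", "nrmse_pct"] == pytest.approx(10.0)

    def test_azimuth_wraps_on_circle(self):
        truth = make_table([0.5, 0.6, 0.7], 2.0)
        pred = make_table([0.5, 0.6, 0.7], 2.0)
        truth.leaves["azimuth_deg"] = [0.0, 359.0, 180.0]
        pred.leaves["azimuth_deg"] = [0.0, 1.0, 180.0]
        rep = evaluate(pred, truth)
        # 1 vs 359 degrees is a 2-degree error, not 358
        assert rep.loc["azimuth_deg", "rmse"] == pytest.approx(
            np.sqrt(4 / 3), rel=1e-6)

    def test_count_mismatch_rejected(self):
        truth = make_table([0.5, 0.6, 0.7], 2.0)
        pred = make_table([0.5, 0.6], 2.0)
        with pytest.raises(ValueError, match="rank matching"):
            evaluate(pred, truth)

    def test_multi_plant_pooling(self):
        t1 = make_table([0.5, 0.6], 1.5, "a")
        t2 = make_table([0.7, 0.8], 2.0, "b")
        rep = evaluate([t1, t2], [t1, t2])
        assert rep.loc["leaf_length_m", "n"] == 4
        assert rep.loc["plant_height_m", "n"] == 2
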