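import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hlurm.datasets import STUDY_TOTAL_HA, load_source_area_table
from hlurm.quantity import (
    QuantityTable,
    SourceAreaTable,
    TransitionEditRule,
    areas_to_cells,
    backcast_quantities,
    edit_transitions,
    fuse_sources,
    normalize_to_total,
)
from hlurm.raster import CategorySchema, GridGeometry, TransitionMatrix


def toy_matrix(cells, names=("A", "B")):
    schema = CategorySchema(tuple((i + 1, n) for i, n in enumerate(names)))
    return TransitionMatrix(schema, schema, np.asarray(cells, dtype=float))


def simple_table(areas, weights, classes=("x",), sources=("s1", "s2")):
    a = pd.DataFrame([areas], index=list(classes), columns=list(sources), dtype=float)
    w = pd.DataFrame([weights], index=list(classes), columns=list(sources), dtype=float)
    return SourceAreaTable(a, w)


class TestFuseSources:
    def test_equal_weights_give_mean(self):
        fused = fuse_sources(simple_table([10.0, 20.0], [0.5, 0.5]))
        assert fused["x"] == pytest.approx(15.0)

    def test_published_arable_fusion(self):
        table = load_source_area_table()
        assert fuse_sources(table)["arable"] == pytest.approx(129966.07, abs=0.01)

    def test_published_water_fusion(self):
        table = load_source_area_table()
        assert fuse_sources(table)["water"] == pytest.approx(9274.14, abs=0.01)

    def test_weight_for_missing_area_rejected(self):
        a = pd.DataFrame([[10.0, np.nan]], index=["x"], columns=["s1", "s2"])
        w = pd.DataFrame([[0.5, 0.5]], index=["x"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="missing area"):
            SourceAreaTable(a, w)

    def test_weights_must_sum_to_one_per_class(self):
        with pytest.raises(ValueError, match="sum"):
            simple_table([10.0, 20.0], [0.5, 0.6])

    def test_override_bypasses_weighting(self):
        a = pd.DataFrame([[np.nan, np.nan]], index=["x"], columns=["s1", "s2"])
        w = a.copy()
        table = SourceAreaTable(a, w, fused_override={"x": 618.69})
        assert fuse_sources(table)["x"] == 618.69


class TestNormalizeToTotal:
    def test_proportional_scaling(self):
        qt = normalize_to_total(pd.Series({"a": 1.0, "b": 1.0, "c": 2.0}), 8.0)
        assert qt.targets.tolist() == [2.0, 2.0, 4.0]

    def test_already_normalized_unchanged(self):
        qt = normalize_to_total(pd.Series({"a": 3.0, "b": 5.0}), 8.0)
        np.testing.assert_allclose(qt.targets, [3.0, 5.0])

    def test_order_preserved(self):
        s = pd.Series({"a": 5.0, "b": 1.0, "c": 3.0})
        qt = normalize_to_total(s, 100.0)
        assert list(qt.targets.sort_values().index) == list(s.sort_values().index)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_to_total(pd.Series({"a": 0.0}), 10.0)

    def test_sum_invariant_exact(self):
        qt = normalize_to_total(pd.Series({"a": 0.37, "b": 9.1, "c": 2.2}), 100.0)
        assert qt.targets.sum() == pytest.approx(100.0, abs=1e-9)


class TestEditTransitions:
    def test_move_all_flow(self):
        m = toy_matrix([[5, 7, 0], [0, 3, 0], [0, 0, 2]], names=("wetland", "arable", "grassland"))
        out = edit_transitions(m, [TransitionEditRule("wetland", "arable", "grassland")])
        assert out.cells[0].tolist() == [5.0, 0.0, 7.0]
        assert out.initial_totals[0] == m.initial_totals[0]

    def test_empty_rule_list_is_identity(self):
        m = toy_matrix([[1, 2], [3, 4]])
        out = edit_transitions(m, [])
        np.testing.assert_array_equal(out.cells, m.cells)

    def test_disjoint_rules_commute(self):
        m = toy_matrix([[1, 2, 3], [4, 5, 6], [7, 8, 9]], names=("A", "B", "C"))
        r1 = TransitionEditRule("A", "B", "C")
        r2 = TransitionEditRule("B", "C", "A")
        out12 = edit_transitions(m, [r1, r2])
        out21 = edit_transitions(m, [r2, r1])
        np.testing.assert_allclose(out12.cells, out21.cells)

    def test_partial_amount(self):
        m = toy_matrix([[1, 10], [0, 1]])
        out = edit_transitions(m, [TransitionEditRule("A", "B", "A", amount=4.0)])
        assert out.cells[0].tolist() == [5.0, 6.0]

    def test_amount_exceeding_flow_rejected(self):
        m = toy_matrix([[1, 2], [0, 1]])
        with pytest.raises(ValueError, match="available"):
            edit_transitions(m, [TransitionEditRule("A", "B", "A", amount=3.0)])

    @given(st.lists(st.sampled_from(["A", "B", "C"]), min_size=3, max_size=3))
    def test_grand_total_preserved(self, picks):
        m = toy_matrix([[1, 2, 3], [4, 5, 6], [7, 8, 9]], names=("A", "B", "C"))
        rules = [TransitionEditRule(picks[0], picks[1], picks[2])]
        assert edit_transitions(m, rules).total == pytest.approx(m.total)


class TestBackcast:
    def test_matching_margins_need_no_rescale(self):
        m = toy_matrix([[2, 0], [1, 1]])
        qt = backcast_quantities(m, pd.Series({"A": 3.0, "B": 1.0}))
        assert qt.targets.tolist() == [2.0, 2.0]

    def test_hand_rescaled_example(self):
        m = toy_matrix([[2, 0], [1, 1]])
        qt = backcast_quantities(m, pd.Series({"A": 6.0, "B": 2.0}))
        assert qt.targets.tolist() == [4.0, 4.0]

    def test_conservation_for_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = toy_matrix(rng.random((3, 3)) + 0.01, names=("A", "B", "C"))
            margins = pd.Series(rng.random(3) * 10, index=["A", "B", "C"])
            qt = backcast_quantities(m, margins)
            assert qt.targets.sum() == pytest.approx(margins.sum())

    def test_zero_column_with_nonzero_margin_rejected(self):
        m = toy_matrix([[2, 0], [1, 0]])
        with pytest.raises(ValueError, match="B"):
            backcast_quantities(m, pd.Series({"A": 3.0, "B": 1.0}))


class TestAreasToCells:
    geom = GridGeometry(1, 3, 90.0)

    def test_exact_split(self):
        qt = QuantityTable(pd.Series({"a": 0.81, "b": 0.81}), 1.62)
        cells = areas_to_cells(qt, self.geom, 2)
        assert cells.tolist() == [1, 1]

    def test_largest_remainder_by_hand(self):
        # 1.0 ha -> 1.235 cells, 1.43 ha -> 1.765 cells: remainders 0.235 < 0.765
        qt = QuantityTable(pd.Series({"a": 1.0, "b": 1.43}), 2.43)
        cells = areas_to_cells(qt, self.geom, 3)
        assert cells.tolist() == [1, 2]

    def test_permutation_equivariant(self):
        qt1 = QuantityTable(pd.Series({"a": 1.0, "b": 1.43}), 2.43)
        qt2 = QuantityTable(pd.Series({"b": 1.43, "a": 1.0}), 2.43)
        c1 = areas_to_cells(qt1, self.geom, 3)
        c2 = areas_to_cells(qt2, self.geom, 3)
        assert c1["a"] == c2["a"] and c1["b"] == c2["b"]

    def test_infeasible_total_rejected(self):
        qt = QuantityTable(pd.Series({"a": 10.0}), 10.0)
        with pytest.raises(ValueError, match="incompatible"):
            areas_to_cells(qt, self.geom, 3)

    def test_quotas_sum_to_cells_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(10, 500))
            raw = pd.Series(rng.random(5) + 0.01, index=list("abcde"))
            qt = normalize_to_total(raw, n * 0.81)
            assert areas_to_cells(qt, GridGeometry(1, n, 90.0), n).sum() == n


class TestPublishedFusion:
    """The packaged multi-source table reproduces every published fused area."""

    EXPECTED = {
        "arable": 129966.07,
        "forest": 675.69,
        "grassland": 335798.79,
        "water": 9274.14,
        "settlement": 3758.57,
        "wetland": 51514.18,
        "other_unused": 618.69,
    }

    def test_each_fused_value(self):
        fused = fuse_sources(load_source_area_table())
        for cls, expect in self.EXPECTED.items():
            assert fused[cls] == pytest.approx(expect, abs=0.01), cls

    def test_fused_sum_matches_study_total(self):
        fused = fuse_sources(load_source_area_table())
        assert fused.sum() == pytest.approx(STUDY_TOTAL_HA, abs=0.02)
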