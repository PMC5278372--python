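import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hlurm.raster import (
    DEFAULT_SCHEMA,
    MERGE_MAPPING,
    MERGED_SCHEMA,
    CategorySchema,
    GeometryMismatchError,
    GridGeometry,
    LandUseGrid,
    UnknownCodeError,
    class_areas,
    crosstab,
    read_raster,
    reclassify,
    trajectory_codes,
    write_raster,
)

from conftest import make_grid


class TestSchema:
    def test_default_schema_has_seven_classes(self):
        assert DEFAULT_SCHEMA.codes == (1, 2, 3, 4, 5, 6, 7)
        assert DEFAULT_SCHEMA.name_of(3) == "grassland"

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            CategorySchema(entries=((1, "a"), (1, "b")))

    def test_nodata_must_differ_from_codes(self):
        with pytest.raises(ValueError, match="nodata"):
            CategorySchema(entries=((1, "a"),), nodata_code=1)

    def test_merged_schema_derivable_via_reclassify(self):
        vals = np.array([[1, 6], [7, 6]])
        grid = make_grid(vals, schema=DEFAULT_SCHEMA)
        merged = reclassify(grid, MERGE_MAPPING, out_schema=MERGED_SCHEMA)
        assert (merged.values == np.array([[1, 6], [6, 6]])).all()
        assert merged.schema.name_of(6) == "unused"


class TestIO:
    @pytest.mark.parametrize("ext", ["asc", "tif"])
    def test_round_trip_identity(self, tmp_path, ext):
        vals = np.arange(1, 8).reshape(1, 7).repeat(3, axis=0) % 7 + 1
        grid = LandUseGrid(
            GridGeometry(3, 7, 90.0, origin=(1000.0, 2000.0)), vals, DEFAULT_SCHEMA
        )
        path = tmp_path / f"g.{ext}"
        write_raster(grid, path)
        back = read_raster(path, DEFAULT_SCHEMA)
        assert back.equals(grid)
        assert back.geometry == grid.geometry

    def test_ascii_nodata_mask(self, tmp_path):
        path = tmp_path / "g.asc"
        path.write_text(
            "ncols 3\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 90\n"
            "NODATA_value -9999\n1 -9999 2\n-9999 3 1\n"
        )
        grid = read_raster(path, DEFAULT_SCHEMA)
        assert grid.valid_mask.tolist() == [[True, False, True], [False, True, True]]

    def test_unknown_code_is_reported(self, tmp_path):
        path = tmp_path / "g.asc"
        path.write_text(
            "ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\ncellsize 90\n"
            "NODATA_value -9999\n1 9\n"
        )
        with pytest.raises(UnknownCodeError, match="9"):
            read_raster(path, DEFAULT_SCHEMA)


class TestReclassify:
    def test_identity_mapping_is_noop(self):
        grid = make_grid([[1, 2], [3, 1]])
        out = reclassify(grid, {c: c for c in grid.schema.codes})
        assert out.equals(grid)

    def test_wetland_merge_counts(self):
        vals = np.array([[6, 6, 7], [6, 6, 1]])
        grid = make_grid(vals, schema=DEFAULT_SCHEMA)
        out = reclassify(grid, MERGE_MAPPING, out_schema=MERGED_SCHEMA)
        areas = class_areas(out)
        assert areas["unused"] == pytest.approx(5 * 0.81)

    def test_partial_mapping_rejected(self):
        grid = make_grid([[1, 2], [3, 1]])
        with pytest.raises(ValueError, match="total"):
            reclassify(grid, {1: 1, 2: 2})

    def test_nodata_preserved(self):
        grid = make_grid([[1, -9999], [2, 3]], schema=DEFAULT_SCHEMA)
        out = reclassify(grid, {c: 1 for c in DEFAULT_SCHEMA.codes})
        assert out.values[0, 1] == out.schema.nodata_code

    @given(
        m1=st.dictionaries(
            st.sampled_from([1, 2, 3]), st.sampled_from([1, 2, 3]), min_size=3
        ).filter(lambda d: set(d) == {1, 2, 3}),
        m2=st.dictionaries(
            st.sampled_from([1, 2, 3]), st.sampled_from([1, 2, 3]), min_size=3
        ).filter(lambda d: set(d) == {1, 2, 3}),
    )
    def test_composition_of_reclassify(self, m1, m2):
        grid = make_grid([[1, 2, 3], [3, 2, 1]])
        two_step = reclassify(reclassify(grid, m1), m2)
        composed = reclassify(grid, {c: m2[m1[c]] for c in (1, 2, 3)})
        assert two_step.equals(composed)


class TestClassAreas:
    def test_all_one_class_90m(self):
        grid = make_grid(np.full((10, 10), 3), schema=DEFAULT_SCHEMA)
        areas = class_areas(grid)
        assert areas["grassland"] == pytest.approx(81.0)
        assert areas.drop("grassland").sum() == 0

    def test_sum_equals_valid_area(self):
        vals = np.array([[1, 2, -9999], [3, 3, 1]])
        grid = make_grid(vals, schema=DEFAULT_SCHEMA)
        assert class_areas(grid).sum() == pytest.approx(5 * 0.81)


class TestCrosstab:
    def test_identical_grids_are_diagonal(self):
        grid = make_grid([[1, 2], [3, 2]])
        tm = crosstab(grid, grid)
        off_diag = tm.cells - np.diag(np.diag(tm.cells))
        assert off_diag.sum() == 0

    def test_hand_counted_2x2(self):
        t1 = make_grid([[1, 1], [2, 2]], cell_size=100.0)
        t2 = make_grid([[1, 2], [2, 2]], cell_size=100.0, schema=t1.schema)
        tm = crosstab(t1, t2)
        assert tm.cells.tolist() == [[1.0, 1.0], [0.0, 2.0]]
        assert tm.gross_loss.tolist() == [1.0, 0.0]
        assert tm.gross_gain.tolist() == [0.0, 1.0]

    def test_margins_match_class_areas(self):
        rng = np.random.default_rng(5)
        t1 = make_grid(rng.integers(1, 4, (20, 20)), schema=DEFAULT_SCHEMA)
        t2 = make_grid(rng.integers(1, 4, (20, 20)), schema=DEFAULT_SCHEMA)
        tm = crosstab(t1, t2)
        np.testing.assert_allclose(tm.initial_totals, class_areas(t1).to_numpy())
        np.testing.assert_allclose(tm.final_totals, class_areas(t2).to_numpy())
        assert tm.total == pytest.approx(class_areas(t1).sum())

    def test_nodata_in_either_grid_excluded(self):
        t1 = make_grid([[1, -9999]], schema=DEFAULT_SCHEMA)
        t2 = make_grid([[1, 1]], schema=DEFAULT_SCHEMA)
        assert crosstab(t1, t2).total == pytest.approx(0.81)

    def test_geometry_mismatch_rejected(self):
        t1 = make_grid([[1, 2]])
        t2 = make_grid([[1], [2]])
        with pytest.raises(GeometryMismatchError):
            crosstab(t1, t2)


class TestTrajectory:
    def test_identical_series_single_trajectory(self):
        grid = make_grid([[1, 2], [2, 1]])
        _, labels, freq, unchanged = trajectory_codes([grid, grid, grid])
        assert len(freq) == 2  # one trajectory per present class
        assert set(labels.values()) == {"1-1-1", "2-2-2"}
        assert (unchanged.dropna() == 1.0).all()

    def test_hand_enumerated_2x1(self):
        t1 = make_grid([[1], [2]])
        t2 = make_grid([[1], [1]], schema=t1.schema)
        _, labels, freq, unchanged = trajectory_codes([t1, t2])
        assert freq.to_dict() == {"1-1": 1, "2-1": 1}
        assert unchanged["class_1"] == 1.0
        assert unchanged["class_2"] == 0.0

    def test_needs_two_grids(self):
        with pytest.raises(ValueError, match="at least 2"):
            trajectory_codes([make_grid([[1]])])

    def test_distinct_trajectories_bounded(self):
        rng = np.random.default_rng(0)
        grids = [
            make_grid(rng.integers(1, 4, (15, 15)), schema=DEFAULT_SCHEMA)
            for _ in range(3)
        ]
        _, labels, _, _ = trajectory_codes(grids)
        assert len(labels) <= 3**3

    def test_unchanged_mask_matches_pairwise_persistence(self):
        rng = np.random.default_rng(1)
        grids = [
            make_grid(rng.integers(1, 3, (10, 10)), schema=DEFAULT_SCHEMA)
            for _ in range(3)
        ]
        traj, labels, _, _ = trajectory_codes(grids)
        same = np.ones((10, 10), dtype=bool)
        for g in grids[1:]:
            same &= grids[0].values == g.values
        constant = np.array(
            [[len(set(labels[traj[r, c]].split("-"))) == 1 for c in range(10)] for r in range(10)]
        )
        assert (constant == same).all()
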