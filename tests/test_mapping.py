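"""Grid assembly, neighbour-mean imputation, canvas interpolation, error maps."""

import numpy as np
import pytest

from nirmap.mapping import (
    BACKGROUND,
    IMPUTED,
    MEASURED,
    GridMap,
    assemble_grid,
    embed_and_interpolate,
    error_map,
    fill_missing_neighbors,
)
from nirmap.synthetic import central_cells_mask


def bfs_fill_oracle(values, measured):
    """Independent sweep simulation of neighbour-mean imputation."""
    vals = values.copy()
    valued = measured.copy()
    rows, cols = vals.shape
    while True:
        new_vals = vals.copy()
        new_valued = valued.copy()
        changed = False
        for r in range(rows):
            for c in range(cols):
                if valued[r, c]:
                    continue
                neigh = [
                    vals[r + dr, c + dc]
                    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
                    if 0 <= r + dr < rows and 0 <= c + dc < cols and valued[r + dr, c + dc]
                ]
                if neigh:
                    new_vals[r, c] = np.mean(neigh)
                    new_valued[r, c] = True
                    changed = True
        vals, valued = new_vals, new_valued
        if not changed:
            return vals, valued


def _grid_from_mask(mask, seed=0):
    rng = np.random.default_rng(seed)
    values = np.where(mask, rng.uniform(70, 75, mask.shape), np.nan)
    coords = [tuple(rc) for rc in np.argwhere(mask)]
    return assemble_grid(values[mask], coords, mask.shape)


class TestAssembleGrid:
    def test_study_mask_counts(self):
        mask = central_cells_mask((9, 14), 55)
        grid = _grid_from_mask(mask)
        assert grid.measured.sum() == 55
        assert (grid.provenance == BACKGROUND).sum() == 71

    def test_full_grid_has_no_background(self):
        mask = np.ones((3, 4), dtype=bool)
        grid = _grid_from_mask(mask)
        assert (grid.provenance == MEASURED).all()

    def test_duplicate_coordinate_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assemble_grid([1.0, 2.0], [(0, 0), (0, 0)], (2, 2))

    def test_out_of_range_coordinate_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            assemble_grid([1.0], [(5, 0)], (2, 2))


class TestFillMissingNeighbors:
    def test_four_neighbour_mean(self):
        vals = np.array([[np.nan, 1.0, np.nan],
                         [4.0, np.nan, 2.0],
                         [np.nan, 3.0, np.nan]])
        mask = ~np.isnan(vals)
        grid = assemble_grid(vals[mask], [tuple(rc) for rc in np.argwhere(mask)], (3, 3))
        filled = fill_missing_neighbors(grid)
        assert filled.values[1, 1] == pytest.approx(2.5)
        assert filled.provenance[1, 1] == IMPUTED

    def test_fully_measured_identity(self):
        grid = _grid_from_mask(np.ones((4, 4), dtype=bool))
        filled = fill_missing_neighbors(grid)
        np.testing.assert_array_equal(filled.values, grid.values)

    def test_matches_bfs_oracle_on_random_masks(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            mask = rng.uniform(size=(6, 8)) < 0.4
            if not mask.any():
                continue
            grid = _grid_from_mask(mask, seed=trial)
            filled = fill_missing_neighbors(grid)
            oracle_vals, oracle_valued = bfs_fill_oracle(grid.values, mask)
            np.testing.assert_allclose(
                filled.values[oracle_valued], oracle_vals[oracle_valued], atol=1e-12
            )
            np.testing.assert_array_equal(filled.provenance != BACKGROUND, oracle_valued)

    def test_multi_sweep_reaches_interior_holes(self):
        # corner cell reachable only through an imputed neighbour
        mask = np.zeros((1, 3), dtype=bool)
        mask[0, 0] = True
        grid = _grid_from_mask(mask)
        filled = fill_missing_neighbors(grid)
        assert (filled.provenance != BACKGROUND).all()
        np.testing.assert_allclose(filled.values, filled.values[0, 0])

    def test_idempotence(self):
        mask = central_cells_mask((9, 14), 55)
        filled = fill_missing_neighbors(_grid_from_mask(mask))
        again = fill_missing_neighbors(filled)
        np.testing.assert_array_equal(filled.values, again.values)
        np.testing.assert_array_equal(filled.provenance, again.provenance)

    def test_imputed_values_within_measured_range(self):
        mask = central_cells_mask((9, 14), 55)
        grid = _grid_from_mask(mask, seed=9)
        filled = fill_missing_neighbors(grid)
        lo, hi = grid.values[mask].min(), grid.values[mask].max()
        imputed = filled.values[filled.provenance == IMPUTED]
        assert imputed.min() >= lo - 1e-12 and imputed.max() <= hi + 1e-12

    def test_zero_measured_rejected(self):
        grid = GridMap(
            np.full((2, 2), np.nan),
            np.zeros((2, 2), dtype=bool),
            np.full((2, 2), BACKGROUND, dtype=object),
        )
        with pytest.raises(ValueError):
            fill_missing_neighbors(grid)

    def test_eight_connectivity_option(self):
        vals = np.array([[1.0, np.nan], [np.nan, 3.0]])
        mask = ~np.isnan(vals)
        grid = assemble_grid(vals[mask], [tuple(rc) for rc in np.argwhere(mask)], (2, 2))
        filled8 = fill_missing_neighbors(grid, connectivity=8)
        assert filled8.values[0, 1] == pytest.approx(2.0)


class TestEmbedAndInterpolate:
    @pytest.mark.parametrize("spacing,expected", [(1.0, 20), (0.5, 39), (0.1, 191), (0.01, 1901)])
    def test_dimension_law(self, spacing, expected):
        grid = fill_missing_neighbors(_grid_from_mask(central_cells_mask((9, 14), 55)))
        cm = embed_and_interpolate(grid, canvas_side=20, spacing=spacing)
        assert cm.interpolated.shape == (expected, expected)

    def test_node_fidelity(self):
        grid = fill_missing_neighbors(_grid_from_mask(central_cells_mask((5, 7), 20)))
        cm = embed_and_interpolate(grid, canvas_side=10, spacing=0.1)
        step = round(1 / 0.1)
        nodes = cm.interpolated[::step, ::step]
        np.testing.assert_allclose(nodes, cm.canvas, atol=1e-12)

    def test_edge_midpoint_is_average(self):
        grid = GridMap(
            np.array([[2.0, 4.0]]),
            np.ones((1, 2), dtype=bool),
            np.full((1, 2), MEASURED, dtype=object),
        )
        cm = embed_and_interpolate(grid, canvas_side=4, spacing=0.5)
        r0, c0 = cm.offset
        row = 2 * r0  # node row of the grid in interpolated coordinates
        mid = cm.interpolated[row, 2 * c0 + 1]
        assert mid == pytest.approx(3.0)

    def test_constant_canvas_interpolates_constant(self):
        grid = GridMap(
            np.full((4, 4), 5.0),
            np.ones((4, 4), dtype=bool),
            np.full((4, 4), MEASURED, dtype=object),
        )
        cm = embed_and_interpolate(grid, canvas_side=4, spacing=0.25, background=5.0)
        np.testing.assert_allclose(cm.interpolated, 5.0, atol=1e-12)

    def test_centering_offset_floor(self):
        grid = fill_missing_neighbors(_grid_from_mask(central_cells_mask((9, 14), 55)))
        cm = embed_and_interpolate(grid, canvas_side=20)
        assert cm.offset == ((20 - 9) // 2, (20 - 14) // 2) == (5, 3)

    def test_grid_larger_than_canvas_rejected(self):
        grid = _grid_from_mask(np.ones((9, 14), dtype=bool))
        with pytest.raises(ValueError):
            embed_and_interpolate(grid, canvas_side=10)


class TestErrorMap:
    def test_identical_grids_zero_errors(self):
        grid = _grid_from_mask(central_cells_mask((9, 14), 55))
        err, summary = error_map(grid, grid)
        assert summary["min"] == summary["max"] == summary["mean"] == summary["median"] == 0.0
        assert summary["n_cells"] == 55

    def test_two_percent_example(self):
        meas = assemble_grid([50.0], [(0, 0)], (1, 2))
        pred = assemble_grid([51.0], [(0, 0)], (1, 2))
        err, summary = error_map(meas, pred)
        assert err[0, 0] == pytest.approx(2.0)

    def test_random_grids_match_direct_recomputation(self):
        rng = np.random.default_rng(4)
        mask = central_cells_mask((9, 14), 55)
        coords = [tuple(rc) for rc in np.argwhere(mask)]
        mv = rng.uniform(60, 80, 55)
        pv = rng.uniform(60, 80, 55)
        err, summary = error_map(
            assemble_grid(mv, coords, (9, 14)), assemble_grid(pv, coords, (9, 14))
        )
        direct = 100 * np.abs(pv - mv) / mv
        assert summary["mean"] == pytest.approx(direct.mean())
        assert summary["median"] == pytest.approx(np.median(direct))
        assert summary["min"] == pytest.approx(direct.min())
        assert summary["max"] == pytest.approx(direct.max())

    def test_zero_measured_cell_excluded(self):
        meas = assemble_grid([0.0, 10.0], [(0, 0), (0, 1)], (1, 2))
        pred = assemble_grid([1.0, 11.0], [(0, 0), (0, 1)], (1, 2))
        err, summary = error_map(meas, pred)
        assert summary["n_excluded_zero"] == 1
        assert summary["n_cells"] == 1

    def test_mask_mismatch_rejected(self):
        a = assemble_grid([1.0], [(0, 0)], (2, 2))
        b = assemble_grid([1.0], [(1, 1)], (2, 2))
        with pytest.raises(ValueError, match="mask"):
            error_map(a, b)
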