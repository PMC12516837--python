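"""Sigma->LV calibration, expert range selection, threshold derivation."""

import numpy as np
import pandas as pd
import pytest

from blurmoe.calibration import (
    ExpertRangeMap,
    GatingTable,
    LVCalibrationTable,
    calibrate_sigma_to_lv,
    derive_lv_thresholds,
    select_expert_ranges,
)
from blurmoe.sharpness import laplacian_variance


class TestCalibrate:
    @pytest.fixture(scope="class")
    def tile_pool(self, default_config):
        import dataclasses
        from blurmoe.synthetic import generate_tile

        cfg = dataclasses.replace(default_config, tile_size=64)
        rng = np.random.default_rng(31)
        return [generate_tile(int(rng.integers(0, 2)), cfg, rng)
                for _ in range(120)]

    def test_sigma_zero_entry_is_raw_median(self, tile_pool):
        grid = [0.0, 1.0, 2.0]
        table = calibrate_sigma_to_lv(tile_pool, grid)
        raw = np.median([laplacian_variance(t) for t in tile_pool])
        assert table.median_for(0.0) == pytest.approx(raw)

    def test_median_lv_strictly_decreasing(self, tile_pool):
        grid = np.arange(0.0, 10.5, 0.5)
        table = calibrate_sigma_to_lv(tile_pool, grid)
        assert (np.diff(table.median_lv) < 0).all()

    def test_deterministic_given_seed(self, tile_pool):
        a = calibrate_sigma_to_lv(tile_pool, [0.0, 2.0], n_sample=110, seed=8)
        b = calibrate_sigma_to_lv(tile_pool, [0.0, 2.0], n_sample=110, seed=8)
        assert np.array_equal(a.median_lv, b.median_lv)

    def test_too_few_tiles_rejected(self, tile_pool):
        with pytest.raises(ValueError, match="100"):
            calibrate_sigma_to_lv(tile_pool[:50], [0.0, 1.0])

    def test_constant_tiles_rejected(self):
        tiles = [np.full((16, 16), 90, dtype=np.uint8)] * 100
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_sigma_to_lv(tiles, [0.0, 1.0])

    def test_json_round_trip(self, tile_pool):
        a = calibrate_sigma_to_lv(tile_pool, [0.0, 1.0, 2.0])
        b = LVCalibrationTable.from_json(a.to_json())
        assert np.array_equal(a.sigmas, b.sigmas)
        assert np.array_equal(a.median_lv, b.median_lv)

    def test_off_grid_lookup_rejected(self, tile_pool):
        table = calibrate_sigma_to_lv(tile_pool, [0.0, 1.0])
        with pytest.raises(KeyError):
            table.median_for(0.25)



class TestSelectExpertRanges:
    def test_two_expert_toy(self):
        mat = pd.DataFrame([[0.9, 0.6], [0.7, 0.8]], index=["E0", "E1"],
                           columns=[0.0, 5.0])
        ranges = select_expert_ranges(mat, {"E0": 0.0, "E1": 5.0})
        assert ranges.entries == [("E0", [0.0]), ("E1", [5.0])]

    def test_dominant_expert_single_interval(self):
        grid = [0.0, 1.0, 2.0, 3.0]
        mat = pd.DataFrame([[0.9, 0.9, 0.9, 0.9], [0.5, 0.6, 0.7, 0.8]],
                           index=["A", "B"], columns=grid)
        ranges = select_expert_ranges(mat, {"A": 0.0, "B": 3.0})
        assert ranges.entries == [("A", grid)]
        assert derive_lv_thresholds(
            LVCalibrationTable(np.array(grid), np.array([400, 300, 200, 100.0]), 100),
            ranges,
        ).thresholds.size == 0

    def test_ties_go_to_lower_training_sigma(self):
        grid = [0.0, 1.0]
        mat = pd.DataFrame([[0.8, 0.8], [0.8, 0.8]], index=["hi", "lo"],
                           columns=grid)
        ranges = select_expert_ranges(mat, {"hi": 5.0, "lo": 0.0})
        assert ranges.entries == [("lo", grid)]

    def test_five_group_cutoff_structure(self):
        # an AUC surface whose column winners reproduce the canonical
        # five-band pattern: baseline below 1.5, then four blur bands
        grid = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0,
                7.0, 8.0, 9.0, 10.0]
        winners = {
            "Base": lambda s: s < 1.5, "M05": lambda s: 1.5 <= s < 2.5,
            "M30": lambda s: 2.5 <= s < 3.5, "M40": lambda s: 3.5 <= s < 5.0,
            "M50": lambda s: s >= 5.0,
        }
        rows = {}
        for name in winners:
            rows[name] = [0.9 if winners[name](s) else 0.6 for s in grid]
        mat = pd.DataFrame(rows).T
        mat.columns = grid
        sig = {"Base": 0.0, "M05": 0.5, "M30": 3.0, "M40": 4.0, "M50": 5.0}
        ranges = select_expert_ranges(mat, sig)
        assert ranges.expert_ids == ["Base", "M05", "M30", "M40", "M50"]
        assert ranges.boundaries() == [(1.0, 1.5), (2.0, 2.5), (3.0, 3.5),
                                       (4.0, 5.0)]

    def test_isolated_winner_smoothed_away(self):
        grid = [0.0, 1.0, 2.0, 3.0, 4.0]
        # B wins only the middle cell, A everywhere else
        mat = pd.DataFrame([[0.9, 0.9, 0.6, 0.9, 0.9],
                            [0.5, 0.5, 0.8, 0.5, 0.5]],
                           index=["A", "B"], columns=grid)
        ranges = select_expert_ranges(mat, {"A": 0.0, "B": 2.0})
        assert ranges.entries == [("A", grid)]

    def test_missing_cell_named(self):
        mat = pd.DataFrame([[0.9, np.nan]], index=["A"], columns=[0.0, 1.0])
        with pytest.raises(ValueError, match="'A'.*1.0"):
            select_expert_ranges(mat, {"A": 0.0})


class TestDeriveThresholds:
    def test_consecutive_median_averaging(self):
        calib = LVCalibrationTable(np.array([1.5, 2.0]),
                                   np.array([400.0, 300.0]), 100)
        ranges = ExpertRangeMap([("A", [1.5]), ("B", [2.0])])
        gating = derive_lv_thresholds(calib, ranges)
        assert gating.thresholds.tolist() == [350.0]
        assert gating.expert_ids == ["A", "B"]

    def test_off_grid_boundary_rejected(self):
        calib = LVCalibrationTable(np.array([0.0, 1.0]),
                                   np.array([400.0, 300.0]), 100)
        ranges = ExpertRangeMap([("A", [0.0]), ("B", [2.0])])
        with pytest.raises(KeyError):
            derive_lv_thresholds(calib, ranges)

    def test_thresholds_decrease_for_decreasing_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            grid = np.sort(rng.uniform(0, 10, size=n))
            meds = np.sort(rng.uniform(1, 1000, size=n))[::-1]
            calib = LVCalibrationTable(grid, meds, 100)
            # random contiguous partition of the grid into 2-4 ranges
            k = int(rng.integers(2, min(5, n)))
            cuts = np.sort(rng.choice(np.arange(1, n), size=k - 1,
                                      replace=False))
            pieces = np.split(np.arange(n), cuts)
            ranges = ExpertRangeMap(
                [(f"E{i}", grid[idx].tolist()) for i, idx in enumerate(pieces)]
            )
            gating = derive_lv_thresholds(calib, ranges)
            assert (np.diff(gating.thresholds) < 0).all() or len(
                gating.thresholds) <= 1

    def test_idempotent(self):
        calib = LVCalibrationTable(np.array([0.0, 1.0, 2.0]),
                                   np.array([500.0, 100.0, 50.0]), 100)
        ranges = ExpertRangeMap([("A", [0.0, 1.0]), ("B", [2.0])])
        a = derive_lv_thresholds(calib, ranges)
        b = derive_lv_thresholds(calib, ranges)
        assert a.to_json() == b.to_json()


class TestRoutingRoundTrip:
    def test_midpoint_sigma_routes_to_owning_expert(self, default_config):
        # tiles blurred at the midpoint of an expert's sigma interval must
        # be routed to that expert for the large majority of tiles
        import dataclasses

        from blurmoe.blur import apply_blur
        from blurmoe.moe import route_tiles
        from blurmoe.synthetic import generate_tile

        cfg = dataclasses.replace(default_config, tile_size=64)
        rng = np.random.default_rng(55)
        tiles = [generate_tile(int(rng.integers(0, 2)), cfg, rng)
                 for _ in range(120)]
        grid = np.arange(0.0, 10.5, 0.5)
        calib = calibrate_sigma_to_lv(tiles, grid)
        ranges = ExpertRangeMap([
            ("sharp", [0.0, 0.5, 1.0, 1.5]),
            ("moderate", list(np.arange(2.0, 5.5, 0.5))),
            ("blurred", list(np.arange(6.0, 10.5, 0.5))),
        ])
        gating = derive_lv_thresholds(calib, ranges)
        mids = {"sharp": 0.75, "moderate": 3.75, "blurred": 8.0}
        for expert, mid in mids.items():
            thetas = {
                f"t{i}": laplacian_variance(apply_blur(t, mid))
                for i, t in enumerate(tiles)
            }
            routing = route_tiles(thetas, gating)
            frac = routing.counts[expert] / routing.n_tot
            assert frac >= 0.9, (expert, frac)
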