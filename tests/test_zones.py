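"""Peripheral/central partitioning and peak-enrichment statistics."""

import numpy as np
import pytest

from ith_niche.grids import MarkerGrid, SquareStatus
from ith_niche.simulate_grids import GridSimConfig, simulate_marker_grid
from ith_niche.zones import (
    bernoulli_peak_test,
    layer_depths,
    peak_zone,
    peripheral_mask,
    zone_square_counts,
    zone_value_compare,
)


def _grid_from_values(values):
    values = np.asarray(values, dtype=float)
    status = np.where(np.isnan(values), SquareStatus.NONTUMOUR, SquareStatus.TUMOUR)
    return MarkerGrid(
        marker="KI67",
        mode="PNC",
        status=status,
        area_fraction=(status > 0).astype(float),
        values=values,
    )


class TestPartition:
    def test_three_by_three_block(self):
        part = peripheral_mask(np.ones((3, 3), bool))
        assert part.n_peripheral == 8 and part.n_central == 1
        assert part.erosion_depth == 2
        assert not part.analysable  # fewer than three layers

    def test_two_row_strip_all_peripheral(self):
        part = peripheral_mask(np.ones((2, 7), bool))
        assert part.n_peripheral == 14 and part.n_central == 0
        assert part.erosion_depth <= 2
        assert not part.analysable

    def test_internal_hole_does_not_create_periphery(self):
        mask = np.ones((5, 5), bool)
        mask[2, 2] = False
        part = peripheral_mask(mask)
        # ring adjacent to the hole stays central; only the outer ring is peripheral
        assert part.n_peripheral == 16
        assert part.n_central == 8
        assert part.central[1, 2] and part.central[2, 1]

    def test_partition_is_disjoint_cover(self):
        for seed in range(5):
            grid, _ = simulate_marker_grid(GridSimConfig(seed=seed))
            part = peripheral_mask(grid)
            assert not (part.peripheral & part.central).any()
            assert np.array_equal(part.peripheral | part.central, grid.tumour_mask)

    def test_peeling_layer_two_is_periphery_of_eroded_tumour(self):
        grid, _ = simulate_marker_grid(GridSimConfig(rows=15, cols=15, seed=8))
        mask = grid.tumour_mask
        depth = layer_depths(mask)
        eroded = mask & (depth >= 2)
        if eroded.any():
            inner = peripheral_mask(eroded)
            assert np.array_equal(inner.peripheral, depth == 2)

    def test_no_tumour_fails(self):
        with pytest.raises(ValueError, match="no tumour"):
            peripheral_mask(np.zeros((4, 4), bool))

    def test_connectivity_four_is_stricter(self):
        # a diagonal exposure counts as outermost only under 8-connectivity
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        mask[0, 0] = True  # diagonal neighbour of (1,1) — still exterior-adjacent
        p8 = peripheral_mask(mask, connectivity=8)
        assert p8.peripheral[1, 1]


class TestPeakZone:
    def test_unique_peripheral_max(self):
        v = np.full((5, 5), 10.0)
        v[0, 2] = 50.0
        grid = _grid_from_values(v)
        part = peripheral_mask(grid)
        assert peak_zone(grid, part) == "peripheral"

    def test_uniform_grid_is_tied(self):
        grid = _grid_from_values(np.full((5, 5), 10.0))
        part = peripheral_mask(grid)
        assert peak_zone(grid, part) == "tied"

    def test_enrichment_recovered_with_low_noise(self):
        hits = 0
        n = 60
        for seed in range(n):
            cfg = GridSimConfig(baseline=10.0, peripheral_delta=20.0, noise_sd=1.0, seed=seed)
            grid, _ = simulate_marker_grid(cfg)
            part = peripheral_mask(grid)
            hits += peak_zone(grid, part) == "peripheral"
        assert hits / n >= 0.99


class TestBernoulliTest:
    def test_zero_peaks_never_significant(self):
        assert bernoulli_peak_test(0, 30) >= 0.99

    def test_all_peaks_closed_form(self):
        # P[X >= 30 | 30, 0.51] = 0.51^30
        assert bernoulli_peak_test(30, 30) == pytest.approx(0.51**30, rel=1e-9)

    def test_expected_count_not_significant(self):
        k = round(30 * 0.51)
        assert 0.4 < bernoulli_peak_test(k, 30) < 0.7

    def test_invalid_counts_fail(self):
        with pytest.raises(ValueError):
            bernoulli_peak_test(31, 30)
        with pytest.raises(ValueError):
            bernoulli_peak_test(5, 30, p_success=1.5)


class TestZoneValueCompare:
    def test_identical_samples_not_significant(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = zone_value_compare(x, x)
        assert p > 0.9

    def test_disjoint_ranges_significant(self, rng):
        a = rng.uniform(0, 1, 10)
        b = rng.uniform(10, 11, 10)
        _, p = zone_value_compare(a, b)
        assert p < 0.001

    def test_single_value_group_fails(self):
        with pytest.raises(ValueError):
            zone_value_compare([1.0], [1.0, 2.0])


class TestExports:
    def test_partition_tsv_and_overlay(self, tmp_path):
        import pandas as pd

        from ith_niche.zones import overlay_export, write_partition_tsv

        grid, _ = simulate_marker_grid(GridSimConfig(seed=8))
        part = peripheral_mask(grid)
        tsv = tmp_path / "zones.tsv"
        write_partition_tsv(part, tsv)
        df = pd.read_csv(tsv, sep="\t").fillna("")
        assert (df.zone == "peripheral").sum() == part.n_peripheral
        assert (df.zone == "central").sum() == part.n_central
        png = tmp_path / "overlay.png"
        overlay_export(grid, part, out_png=str(png))
        assert png.exists()


class TestZoneCounts:
    def test_single_and_additive_counts(self):
        one = peripheral_mask(np.ones((3, 3), bool))
        n_p, n_c, frac = zone_square_counts([one])
        assert (n_p, n_c) == (8, 1)
        n_p2, n_c2, _ = zone_square_counts([one, one])
        assert (n_p2, n_c2) == (16, 2)

    def test_balanced_construction_gives_half(self):
        # 7x7 block: 24 peripheral vs 25 central squares
        part = peripheral_mask(np.ones((7, 7), bool))
        _, _, frac = zone_square_counts([part])
        assert frac == pytest.approx(24 / 49)
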