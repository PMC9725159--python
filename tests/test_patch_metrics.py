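import numpy as np
import pytest

from _oracles import bf_adjacency, bf_contig, bf_label, bf_pladj, bf_shei
from mangrove_health.patch_metrics import (
    adjacency_counts,
    adjacency_matrix,
    contig,
    contig_values,
    label_grid,
    label_patches,
    patch_density,
    pladj,
    shei,
    shei_value,
)
from mangrove_health.raster_io import CategoricalRaster, RasterValidationError


def cat(grid, legend, pixel=1.5):
    return CategoricalRaster(np.asarray(grid, np.int32), pixel, legend)


class TestLabeling:
    def test_uniform_block_single_patch(self, legend2):
        ps = label_patches(cat(np.ones((5, 5)), legend2))
        assert ps.patches == [(1, 1, 25)]

    def test_checkerboard_diagonals_do_not_connect(self, legend2):
        grid = np.indices((4, 4)).sum(axis=0) % 2 + 1
        ps = label_patches(cat(grid, legend2))
        assert ps.n_patches == 16
        assert all(a == 1 for _, _, a in ps.patches)

    def test_corner_touching_blocks_are_two_patches(self, legend2):
        grid = np.full((4, 4), 2)
        grid[:2, :2] = 1
        grid[2:, 2:] = 1
        ps = label_patches(cat(grid, legend2))
        assert len(ps.ids_of_class(1)) == 2

    def test_all_nodata_rejected(self, legend2):
        with pytest.raises(RasterValidationError):
            label_patches(cat(np.zeros((3, 3)), legend2))

    def test_matches_flood_fill_on_random_grids(self, make_raster):
        for seed in range(10):
            raster = make_raster(shape=(15, 15), seed=seed, nodata_frac=0.15)
            labels, classes, areas = label_grid(raster.grid, 0)
            _, bf_classes, bf_areas = bf_label(raster.grid, 0)
            assert sorted(zip(classes, areas)) == sorted(zip(bf_classes, bf_areas))


class TestAdjacency:
    def test_uniform_3x3_double_counts(self, legend2):
        table = adjacency_counts(cat(np.ones((3, 3)), legend2))
        assert table.like(1) == 24  # 12 orthogonal pairs, each counted twice

    def test_single_pair_counted_from_both_sides(self, legend2):
        table = adjacency_counts(cat([[1, 2]], legend2))
        assert table.g.tolist() == [[0, 1], [1, 0]]

    def test_half_split_counts(self, legend2):
        grid = np.ones((4, 4))
        grid[:, 2:] = 2
        table = adjacency_counts(cat(grid, legend2))
        assert table.like(1) == 20
        i, j = table.codes.index(1), table.codes.index(2)
        assert table.g[i, j] == 4  # from A's side

    def test_matches_enumeration_on_random_grids(self, make_raster):
        for seed in range(20):
            raster = make_raster(shape=(14, 14), seed=seed, nodata_frac=0.1)
            codes, g = adjacency_matrix(raster.grid, 0)
            oracle = bf_adjacency(raster.grid, 0)
            for ia, a in enumerate(codes):
                for ib, b in enumerate(codes):
                    assert g[ia, ib] == oracle.get((a, b), 0)

    def test_symmetric_total(self, make_raster):
        raster = make_raster(shape=(12, 12), seed=3)
        _, g = adjacency_matrix(raster.grid, 0)
        np.testing.assert_array_equal(g, g.T)


class TestContig:
    def test_single_pixel_patch_is_zero(self, legend2):
        grid = np.full((3, 3), 2)
        grid[1, 1] = 1
        ps = label_patches(cat(grid, legend2))
        pid = ps.ids_of_class(1)[0]
        assert contig(ps, pid).value == 0.0

    def test_2x2_square_is_5_twelfths(self, legend2):
        grid = np.full((4, 4), 2)
        grid[1:3, 1:3] = 1
        ps = label_patches(cat(grid, legend2))
        pid = ps.ids_of_class(1)[0]
        assert contig(ps, pid).value == pytest.approx(5 / 12)

    def test_large_solid_square_approaches_one(self, legend2):
        ps = label_patches(cat(np.ones((60, 60)), legend2))
        assert contig(ps, 1).value > 0.9

    def test_unknown_patch_id_rejected(self, legend2):
        ps = label_patches(cat(np.ones((3, 3)), legend2))
        with pytest.raises(KeyError):
            contig(ps, 42)

    def test_same_class_different_patch_does_not_contribute(self, legend2):
        # two diagonal same-class pixels: separate patches, both CONTIG 0
        grid = np.full((3, 3), 2)
        grid[0, 0] = grid[1, 1] = 1
        ps = label_patches(cat(grid, legend2))
        for pid in ps.ids_of_class(1):
            assert contig(ps, pid).value == 0.0

    def test_matches_brute_force_on_random_grids(self, make_raster):
        for seed in range(10):
            raster = make_raster(shape=(15, 15), seed=seed, nodata_frac=0.1)
            labels, classes, areas = label_grid(raster.grid, 0)
            values = contig_values(labels, areas)
            for pid in range(1, len(areas) + 1):
                assert values[pid - 1] == pytest.approx(bf_contig(labels, pid))


class TestPladj:
    def test_uniform_is_100(self, legend2):
        table = adjacency_counts(cat(np.ones((6, 6)), legend2))
        assert pladj(table, 1).value == 100.0
        assert pladj(table).value == 100.0

    def test_half_split_class_value(self, legend2):
        grid = np.ones((4, 4))
        grid[:, 2:] = 2
        table = adjacency_counts(cat(grid, legend2))
        assert pladj(table, 1).value == pytest.approx(100 * 20 / 24)

    def test_iid_two_class_field_near_50(self, legend2):
        rng = np.random.default_rng(11)
        grid = rng.integers(1, 3, size=(200, 200))
        table = adjacency_counts(cat(grid, legend2))
        assert pladj(table).value == pytest.approx(50.0, abs=2.0)

    def test_relabeling_invariance(self, make_raster, legend6):
        raster = make_raster(shape=(12, 12), seed=5, n_classes=3)
        table = adjacency_counts(raster)
        # swap codes 1<->3 everywhere
        swapped = raster.grid.copy()
        swapped[raster.grid == 1] = 3
        swapped[raster.grid == 3] = 1
        table2 = adjacency_counts(cat(swapped, legend6))
        assert pladj(table, 1).value == pytest.approx(pladj(table2, 3).value)
        assert pladj(table).value == pytest.approx(pladj(table2).value)

    def test_absent_class_undefined(self, legend2):
        table = adjacency_counts(cat(np.ones((3, 3)), legend2))
        assert np.isnan(pladj(table, 2).value)


class TestPatchDensity:
    def test_one_patch_per_hectare(self):
        assert patch_density(1, 10_000.0).value == 1.0

    def test_direct_substitution(self):
        # 5 patches on 100x100 cells at 10 m -> 1e6 m2
        assert patch_density(5, 1_000_000.0).value == pytest.approx(0.05)

    def test_linearity_in_patch_count(self):
        assert patch_density(8, 5e4).value == 2 * patch_density(4, 5e4).value

    def test_per_100ha_scale(self):
        assert patch_density(1, 10_000.0, per_100ha=True).value == 100.0

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            patch_density(1, 0.0)

    def test_exact_count_recovery(self, make_raster):
        raster = make_raster(shape=(10, 10), seed=2)
        from mangrove_health.patch_metrics import label_patches as lp

        ps = lp(raster)
        area = 100 * raster.pixel_size_m**2
        pd_val = patch_density(ps, area).value
        assert round(pd_val * area / 10_000.0) == ps.n_patches


class TestShei:
    def test_single_class_is_zero(self, legend2):
        assert shei(cat(np.ones((4, 4)), legend2)).value == 0.0

    def test_two_equal_classes_is_one(self, legend2):
        assert shei(cat([[1, 2], [1, 2]], legend2)).value == pytest.approx(1.0)

    def test_three_class_example(self, legend6):
        grid = np.array([[1, 1], [2, 3]])
        assert shei(cat(grid, legend6)).value == pytest.approx(0.9464, abs=1e-4)

    def test_permutation_invariance(self, legend6):
        g1 = np.repeat([1, 2, 3], [6, 3, 3]).reshape(3, 4)
        g2 = np.repeat([1, 2, 3], [3, 6, 3]).reshape(3, 4)
        assert shei(cat(g1, legend6)).value == pytest.approx(
            shei(cat(g2, legend6)).value
        )

    def test_subset_restriction_matches_oracle(self, make_raster):
        raster = make_raster(shape=(12, 12), seed=9)
        got = shei_value(raster.grid, 0, subset=(1, 2))
        assert got == pytest.approx(bf_shei(raster.grid, 0, subset=(1, 2)))

    def test_matches_oracle_on_random_grids(self, make_raster):
        for seed in range(10):
            raster = make_raster(shape=(10, 10), seed=seed, nodata_frac=0.2)
            assert shei_value(raster.grid, 0) == pytest.approx(
                bf_shei(raster.grid, 0)
            )


def test_metric_ranges_on_random_landscapes(make_raster):
    """All four metrics stay inside their declared ranges."""
    from mangrove_health.patch_metrics import label_patches as lp

    for seed in range(50):
        raster = make_raster(shape=(10, 10), seed=seed, nodata_frac=0.1)
        if not raster.valid_mask.any():
            continue
        table = adjacency_counts(raster)
        v = pladj(table).value
        assert np.isnan(v) or 0 <= v <= 100
        ps = lp(raster)
        labels, _, areas = label_grid(raster.grid, 0)
        cv = contig_values(labels, areas)
        assert ((cv >= -1e-12) & (cv <= 1 + 1e-12)).all()
        s = shei(raster).value
        assert 0 <= s <= 1 + 1e-12
        area = float(raster.valid_mask.sum()) * raster.pixel_size_m**2
        assert patch_density(ps, area).value > 0
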