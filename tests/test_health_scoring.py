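import numpy as np
import pytest

from mangrove_health.health_scoring import (
    DEFAULT_MHI_BINS,
    MembershipTable,
    PairwiseMatrix,
    RankThresholds,
    WeightVector,
    ahp_weights,
    classify_mhi,
    default_thresholds,
    mhi_map,
    rank_factor,
    thresholds_from_quantiles,
    weights_from_membership,
)
from mangrove_health.raster_io import FactorRaster, RankRaster


class TestAhpWeights:
    def test_all_ones_matrix_gives_equal_weights(self):
        pm = PairwiseMatrix(np.ones((4, 4)), ("a", "b", "c", "d"))
        np.testing.assert_allclose(ahp_weights(pm).w, 0.25)

    def test_two_factor_hand_example(self):
        pm = PairwiseMatrix(np.array([[1, 4], [0.25, 1]]), ("a", "b"))
        np.testing.assert_allclose(ahp_weights(pm).w, [0.8, 0.2])

    def test_consistent_matrix_recovers_ratio_vector(self):
        w = (0.3, 0.4, 0.2, 0.1)
        pm = PairwiseMatrix.from_ratios(w, "cfdd")
        np.testing.assert_allclose(ahp_weights(pm).w, w, atol=1e-12)

    def test_weights_sum_to_one_on_random_reciprocal_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            upper = rng.uniform(0.25, 4.0, size=6)
            m = np.eye(4)
            idx = np.triu_indices(4, 1)
            m[idx] = upper
            m[(idx[1], idx[0])] = 1.0 / upper
            wv = ahp_weights(PairwiseMatrix(m, "abcd"))
            assert wv.w.sum() == pytest.approx(1.0)
            assert (wv.w >= 0).all()

    def test_non_reciprocal_rejected(self):
        with pytest.raises(ValueError, match="reciprocal"):
            PairwiseMatrix(np.array([[1, 2], [1, 1]]), ("a", "b"))

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            PairwiseMatrix(np.array([[1, 9], [1 / 9, 1]]), ("a", "b"))


class TestMembership:
    def test_degenerate_membership_hits_score(self):
        mt = MembershipTable(np.array([[1.0, 0, 0, 0]]))
        assert weights_from_membership(mt)[0] == 4.0

    def test_uniform_membership_gives_mean_score(self):
        mt = MembershipTable(np.full((1, 4), 0.25))
        assert weights_from_membership(mt)[0] == pytest.approx(2.5)

    def test_direct_arithmetic(self):
        mt = MembershipTable(np.array([[0.5, 0.3, 0.2, 0.0]]))
        assert weights_from_membership(mt)[0] == pytest.approx(3.3)

    def test_row_not_summing_to_one_rejected(self):
        with pytest.raises(ValueError):
            MembershipTable(np.array([[0.5, 0.5, 0.5, 0.0]]))


class TestRankThresholds:
    def test_fragmentation_pladj_85_ranks_4(self):
        th = default_thresholds()["fragmentation"]
        assert th.rank_of(np.array([85.0]))[0] == 4

    def test_fragmentation_pladj_49_ranks_1(self):
        th = default_thresholds()["fragmentation"]
        assert th.rank_of(np.array([49.0]))[0] == 1

    @pytest.mark.parametrize(
        "value,rank", [(100.0, 4), (80.0, 4), (79.9, 3), (65.0, 3), (50.0, 2), (0.0, 1)]
    )
    def test_fragmentation_boundaries(self, value, rank):
        th = default_thresholds()["fragmentation"]
        assert th.rank_of(np.array([value]))[0] == rank

    def test_constant_factor_gives_constant_ranks(self):
        th = default_thresholds()["canopy_width"]
        fr = FactorRaster(np.full((4, 4), 0.6), 1.5, "canopy_width")
        rr = rank_factor(fr, th)
        assert (rr.grid == 3).all()

    def test_order_of_intervals_irrelevant(self):
        a = RankThresholds("x", ((0, 50, 1), (50, 100, 4)))
        b = RankThresholds("x", ((50, 100, 4), (0, 50, 1)))
        vals = np.array([10.0, 75.0, 100.0])
        np.testing.assert_array_equal(a.rank_of(vals), b.rank_of(vals))

    def test_out_of_range_value_named(self):
        th = default_thresholds()["canopy_width"]
        with pytest.raises(ValueError, match="7.0"):
            th.rank_of(np.array([7.0]))

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RankThresholds("x", ((0, 60, 1), (50, 100, 2)))

    def test_nan_propagates_as_nodata(self):
        th = default_thresholds()["fragmentation"]
        fr = FactorRaster(np.array([[np.nan, 90.0]]), 1.5)
        rr = rank_factor(fr, th)
        assert rr.grid.tolist() == [[0, 4]]

    def test_quantile_calibration_covers_scene(self):
        rng = np.random.default_rng(1)
        fr = FactorRaster(rng.uniform(0, 3, (20, 20)), 1.5, "density")
        th = thresholds_from_quantiles(fr)
        ranks = th.rank_of(fr.grid)
        assert set(np.unique(ranks)) == {1, 2, 3, 4}
        # roughly equal class shares by construction
        counts = np.bincount(ranks.ravel(), minlength=5)[1:]
        assert counts.min() > 0.15 * ranks.size


def rank_raster(grid):
    return RankRaster(np.asarray(grid, np.int32), 1.5)


class TestMhi:
    def test_worked_example(self):
        ranks = [rank_raster([[r]]) for r in (2, 3, 4, 1)]
        wv = WeightVector(np.array([0.3, 0.4, 0.2, 0.1]), ("c", "f", "d", "v"))
        assert mhi_map(ranks, wv).grid[0, 0] == pytest.approx(2.7)

    @pytest.mark.parametrize("rank,expect", [(4, 4.0), (1, 1.0)])
    def test_bounds_attained_at_uniform_ranks(self, rank, expect):
        ranks = [rank_raster(np.full((3, 3), rank)) for _ in range(4)]
        wv = WeightVector(np.full(4, 0.25), "abcd")
        np.testing.assert_allclose(mhi_map(ranks, wv).grid, expect)

    def test_bounds_on_random_stacks(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            ranks = [rank_raster(rng.integers(1, 5, (3, 3))) for _ in range(4)]
            w = rng.dirichlet(np.ones(4))
            mhi = mhi_map(ranks, WeightVector(w, "abcd"))
            stack = np.stack([r.grid for r in ranks])
            assert (mhi.grid >= stack.min(axis=0) - 1e-12).all()
            assert (mhi.grid <= stack.max(axis=0) + 1e-12).all()

    def test_monotone_in_single_factor_rank(self):
        """Raising any one factor's rank at any cell never lowers MHI."""
        rng = np.random.default_rng(3)
        base = [rank_raster(rng.integers(1, 5, (3, 3))) for _ in range(4)]
        wv = WeightVector(rng.dirichlet(np.ones(4)), "abcd")
        mhi0 = mhi_map(base, wv).grid
        for f in range(4):
            for r in range(3):
                for c in range(3):
                    if base[f].grid[r, c] == 4:
                        continue
                    bumped = [rank_raster(x.grid.copy()) for x in base]
                    bumped[f].grid[r, c] += 1
                    mhi1 = mhi_map(bumped, wv).grid
                    assert mhi1[r, c] >= mhi0[r, c] - 1e-12

    def test_nodata_propagates(self):
        ranks = [rank_raster([[1, 2]]) for _ in range(4)]
        ranks[2] = rank_raster([[0, 2]])  # nodata at cell 0
        wv = WeightVector(np.full(4, 0.25), "abcd")
        out = mhi_map(ranks, wv)
        assert np.isnan(out.grid[0, 0]) and out.grid[0, 1] == 2.0


class TestClassifyMhi:
    @pytest.mark.parametrize("value,cls", [(1.0, 1), (4.0, 4), (2.7, 3), (1.75, 2)])
    def test_default_bins(self, value, cls):
        fr = FactorRaster(np.array([[value]]), 1.5, "MHI")
        assert classify_mhi(fr).grid[0, 0] == cls

    def test_out_of_range_rejected(self):
        fr = FactorRaster(np.array([[4.5]]), 1.5, "MHI")
        with pytest.raises(ValueError):
            classify_mhi(fr)

    def test_bins_cover_whole_interval(self):
        rng = np.random.default_rng(4)
        fr = FactorRaster(rng.uniform(1, 4, (10, 10)), 1.5, "MHI")
        out = classify_mhi(fr)
        assert set(np.unique(out.grid)) <= {1, 2, 3, 4}
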