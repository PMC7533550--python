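"""Scalar tests, t maps, TFCE and permutation FWE against closed-form oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from fcslat.grid import BinaryMask, ImageGrid, ScalarMap
from fcslat.stats import (
    StatMap,
    bonferroni_posthoc,
    chi_square_2x2,
    extract_clusters,
    paired_t,
    partial_correlation,
    permutation_fwe,
    rm_anova_oneway,
    tfce_transform,
    two_sample_t_map,
    two_sample_t_summary,
)


def _maps(grid, data):
    """Stack (n_subjects, *dims) into a list of ScalarMaps."""
    return [ScalarMap(grid, d) for d in data]


class TestTwoSampleT:
    def test_identical_groups_give_zero(self, rng):
        grid = ImageGrid((3, 3, 2))
        mask = BinaryMask(grid, np.ones(grid.dims, bool))
        data = rng.standard_normal((3,) + grid.dims)
        out = two_sample_t_map(_maps(grid, data), _maps(grid, data.copy()), mask)
        np.testing.assert_allclose(out.values.values, 0.0, atol=1e-10)

    def test_swapping_groups_negates_map(self, rng):
        grid = ImageGrid((3, 3, 2))
        mask = BinaryMask(grid, np.ones(grid.dims, bool))
        a = rng.standard_normal((4,) + grid.dims)
        b = rng.standard_normal((5,) + grid.dims)
        ab = two_sample_t_map(_maps(grid, a), _maps(grid, b), mask)
        ba = two_sample_t_map(_maps(grid, b), _maps(grid, a), mask)
        np.testing.assert_allclose(ab.values.values, -ba.values.values, atol=1e-12)
        assert ab.df == 7

    def test_hand_fixture_single_voxel(self):
        grid = ImageGrid((1, 1, 1))
        mask = BinaryMask(grid, np.ones(grid.dims, bool))
        a = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1)
        b = np.array([4.0, 5.0, 6.0]).reshape(3, 1, 1, 1)
        out = two_sample_t_map(_maps(grid, a), _maps(grid, b), mask)
        assert out.values.values[0, 0, 0] == pytest.approx(-3.674, abs=5e-4)
        assert out.df == 4

    def test_map_t_equals_summary_t_at_each_voxel(self, rng):
        # internal consistency between the map and summary-statistic paths
        grid = ImageGrid((2, 2, 1))
        mask = BinaryMask(grid, np.ones(grid.dims, bool))
        a = rng.standard_normal((6,) + grid.dims)
        b = rng.standard_normal((8,) + grid.dims)
        out = two_sample_t_map(_maps(grid, a), _maps(grid, b), mask)
        for idx in np.ndindex(grid.dims):
            va, vb = a[(slice(None),) + idx], b[(slice(None),) + idx]
            t, df = two_sample_t_summary(va.mean(), va.std(ddof=1), 6,
                                         vb.mean(), vb.std(ddof=1), 8)
            assert out.values.values[idx] == pytest.approx(t, abs=1e-10)


class TestSummaryT:
    def test_cohort_age_row(self):
        # group summaries 52.73 +/- 10.51 (n=25) vs 51.84 +/- 8.06 (n=26)
        t, df = two_sample_t_summary(52.73, 10.51, 25, 51.84, 8.06, 26)
        assert round(t, 2) == 0.34
        assert df == 49

    def test_equal_means_give_zero(self):
        assert two_sample_t_summary(5.0, 1.0, 10, 5.0, 2.0, 12)[0] == 0.0

    def test_hand_value(self):
        t, _ = two_sample_t_summary(10, 2, 10, 8, 2, 10)
        assert t == pytest.approx(2.236, abs=5e-4)

    def test_degenerate_zero_sd(self):
        assert two_sample_t_summary(1.0, 0.0, 5, 1.0, 0.0, 5) == (0.0, 8)
        t, _ = two_sample_t_summary(2.0, 0.0, 5, 1.0, 0.0, 5)
        assert math.isinf(t)


class TestTfce:
    def test_all_zero_map(self):
        assert not tfce_transform(np.zeros((4, 4, 4))).any()

    def test_single_voxel_closed_form(self):
        # isolated voxel of height 2: enhancement -> integral of h^2 = 8/3
        arr = np.zeros((5, 5, 5))
        arr[2, 2, 2] = 2.0
        out = tfce_transform(arr, n_steps=100)
        assert out[2, 2, 2] == pytest.approx(8.0 / 3.0, rel=0.05)

    def test_monotone_in_scale(self, rng):
        arr = np.abs(rng.standard_normal((5, 5, 3)))
        lo = tfce_transform(arr)
        hi = tfce_transform(1.5 * arr)
        assert (hi[lo > 0] > lo[lo > 0]).all()
        assert hi.sum() > lo.sum()

    def test_convergence_in_steps(self):
        # smooth blob: doubling the step count changes the enhancement by
        # < 1% of the map scale (each voxel's integral ends at its own
        # height, so the endpoint step keeps per-voxel changes at O(dh))
        x, y, z = np.meshgrid(*[np.linspace(-1, 1, 12)] * 3, indexing="ij")
        arr = np.exp(-(x**2 + y**2 + z**2) * 3)
        a = tfce_transform(arr, n_steps=100)
        b = tfce_transform(arr, n_steps=200)
        assert np.abs(a - b).max() / a.max() < 0.01

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            tfce_transform(np.full((3, 3, 3), -1.0))


class TestPermutationFwe:
    def _make(self, rng, n_a, n_b, dims=(6, 6, 2), effect=0.0, block=None):
        grid = ImageGrid(dims)
        mask = BinaryMask(grid, np.ones(dims, bool))
        a = rng.standard_normal((n_a,) + dims)
        if effect:
            sl = block or (slice(0, 3), slice(0, 3), slice(0, 2))
            a[(slice(None),) + sl] += effect
        b = rng.standard_normal((n_b,) + dims)
        return _maps(grid, a), _maps(grid, b), mask

    def test_p_lower_bound(self, rng):
        a, b, mask = self._make(rng, 5, 5)
        res = permutation_fwe(a, b, mask, n_permutations=100, seed=0)
        assert (res.p_fwe.values[mask.membership] >= 1.0 / res.n_permutations).all()

    def test_seed_reproducibility(self, rng):
        a, b, mask = self._make(rng, 5, 5)
        r1 = permutation_fwe(a, b, mask, n_permutations=120, seed=9)
        r2 = permutation_fwe(a, b, mask, n_permutations=120, seed=9)
        np.testing.assert_array_equal(r1.p_fwe.values, r2.p_fwe.values)
        np.testing.assert_array_equal(r1.null_max, r2.null_max)

    def test_planted_large_effect_detected(self, rng):
        # 5-SD offset in a 27-voxel block: every block voxel survives FWE
        grid = ImageGrid((8, 8, 8))
        mask = BinaryMask(grid, np.ones(grid.dims, bool))
        block = (slice(2, 5), slice(2, 5), slice(2, 5))
        a = rng.standard_normal((8,) + grid.dims)
        a[(slice(None),) + block] += 5.0
        b = rng.standard_normal((8,) + grid.dims)
        res = permutation_fwe(_maps(grid, a), _maps(grid, b), mask,
                              n_permutations=500, seed=3)
        assert (res.p_fwe.values[block] < 0.05).all()

    def test_exhaustive_enumeration_small_groups(self, rng):
        a, b, mask = self._make(rng, 3, 3, dims=(3, 3, 1))
        res = permutation_fwe(a, b, mask, n_permutations=100, seed=0)
        assert res.exhaustive
        assert res.n_permutations == math.comb(6, 3)


class TestRmAnova:
    def test_constant_within_subject_gives_zero_f(self):
        table = np.tile([[3.0], [5.0], [9.0]], (1, 4))
        assert rm_anova_oneway(table)["F"] == 0.0

    def test_perfectly_consistent_shift_flags_infinite_f(self):
        table = np.array([[1.0, 2, 3], [2, 3, 4], [3, 4, 5]])
        res = rm_anova_oneway(table)
        assert res["ms_visit"] == pytest.approx(3.0)
        assert res["ms_error"] == pytest.approx(0.0, abs=1e-12)
        assert math.isinf(res["F"])

    def test_matches_scipy_reference(self, rng):
        # cross-check the sums-of-squares path against an independent F
        x = rng.standard_normal((12, 4)) + rng.standard_normal((12, 1))
        res = rm_anova_oneway(x)
        # independent computation: two-way ANOVA decomposition by scipy-style formulas
        grand = x.mean()
        ss_v = 12 * ((x.mean(0) - grand) ** 2).sum()
        ss_s = 4 * ((x.mean(1) - grand) ** 2).sum()
        ss_e = ((x - grand) ** 2).sum() - ss_v - ss_s
        f = (ss_v / 3) / (ss_e / 33)
        assert res["F"] == pytest.approx(f, rel=1e-12)
        assert res["p"] == pytest.approx(float(sps.f.sf(f, 3, 33)), rel=1e-12)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(2024)
        ps = [rm_anova_oneway(rng.standard_normal((20, 5)))["p"] for _ in range(1000)]
        ks = sps.kstest(ps, "uniform").statistic
        assert ks < 1.63 / math.sqrt(1000)  # critical value at alpha = 0.01

    def test_missing_cells_rejected(self):
        x = np.ones((4, 3))
        x[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_oneway(x)


class TestPostHoc:
    def test_five_visits_give_ten_pairs(self, rng):
        table = rng.standard_normal((6, 5))
        out = bonferroni_posthoc(table)
        assert len(out) == 10

    def test_identical_pair_t_zero_adjusted_one(self, rng):
        table = rng.standard_normal((5, 3))
        table[:, 1] = table[:, 0]
        out = bonferroni_posthoc(table)
        row = out[(out.a == "v0") & (out.b == "v1")].iloc[0]
        assert row.t == 0.0 and row.p_bonferroni == 1.0

    def test_adjustment_is_raw_times_pairs(self, rng):
        table = rng.standard_normal((8, 4))
        out = bonferroni_posthoc(table)
        np.testing.assert_allclose(
            out.p_bonferroni, np.minimum(1.0, out.p_raw * 6), atol=1e-12)


class TestPairedT:
    def test_identical_series_zero(self, rng):
        x = rng.standard_normal(6)
        assert paired_t(x, x)["t"] == 0.0

    def test_constant_nonzero_difference_flags_infinite(self):
        res = paired_t(np.array([2.0, 3, 4, 5]), np.array([1.0, 2, 3, 4]))
        assert res["infinite"] and math.isinf(res["t"])

    def test_hand_fixture(self):
        res = paired_t(np.array([1.0, 2, 3]), np.array([2.0, 4, 6]))
        assert res["t"] == pytest.approx(-3.464, abs=5e-4)
        assert res["df"] == 2


class TestChiSquare:
    def test_proportional_table_zero(self):
        assert chi_square_2x2(10, 5, 20, 10)["chi2"] == 0.0

    def test_perfect_association(self):
        assert chi_square_2x2(10, 0, 0, 10)["chi2"] == pytest.approx(20.0)

    def test_pearson_formula_on_sex_table(self):
        # 18/7 vs 15/11 by the plain Pearson statistic
        assert chi_square_2x2(18, 7, 15, 11)["chi2"] == pytest.approx(1.14, abs=5e-3)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(0, 0, 5, 5)


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x = rng.standard_normal(30)
        y = 0.5 * x + rng.standard_normal(30)
        res = partial_correlation(x, y)
        assert res["r"] == pytest.approx(sps.pearsonr(x, y)[0], abs=1e-12)
        assert res["df"] == 28

    def test_identical_variables_give_one(self, rng):
        x = rng.standard_normal(20)
        z = rng.standard_normal(20)
        assert partial_correlation(x, x, z)["r"] == pytest.approx(1.0)

    def test_y_equal_to_covariate_gives_zero(self, rng):
        x = rng.standard_normal(25)
        z = rng.standard_normal(25)
        res = partial_correlation(x, z, z)
        assert abs(res["r"]) < 1e-10

    def test_collinear_covariates_rejected(self, rng):
        z = rng.standard_normal(15)
        cov = np.column_stack([z, 2 * z])
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(rng.standard_normal(15), rng.standard_normal(15), cov)


class TestExtractClusters:
    def _setup(self, sig_voxels, tvals=None):
        grid = ImageGrid((8, 8, 4))
        p = np.ones(grid.dims)
        t = np.zeros(grid.dims)
        for v in sig_voxels:
            p[v] = 0.01
            t[v] = 3.0 if tvals is None else tvals[v]
        mask = BinaryMask(grid, np.ones(grid.dims, bool))
        stat = StatMap(ScalarMap(grid, t), df=10, mask=mask)
        return ScalarMap(grid, p), stat

    def test_empty_when_nothing_significant(self):
        p, stat = self._setup([])
        assert len(extract_clusters(p, stat)) == 0

    def test_single_block_voxel_count(self):
        voxels = [(x, y, z) for x in range(2, 5) for y in range(2, 5) for z in range(1, 4)]
        p, stat = self._setup(voxels)
        out = extract_clusters(p, stat)
        assert len(out) == 1
        assert out.iloc[0].voxel_number == 27

    def test_corner_touching_blocks_split_by_connectivity(self):
        voxels = [(1, 1, 1), (2, 2, 2)]  # touch only at a corner
        p, stat = self._setup(voxels)
        assert len(extract_clusters(p, stat, connectivity=26)) == 1
        assert len(extract_clusters(p, stat, connectivity=6)) == 2

    def test_peak_coordinates_in_mm_from_grid_centre(self):
        p, stat = self._setup([(4, 4, 2)])
        row = extract_clusters(p, stat).iloc[0]
        # centre of an (8,8,4) 3mm grid is (3.5, 3.5, 1.5)
        assert (row.peak_x_mm, row.peak_y_mm, row.peak_z_mm) == (1.5, 1.5, 1.5)
        assert row.peak_t == 3.0
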