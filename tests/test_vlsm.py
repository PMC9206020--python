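"""Voxelwise rank test, FDR/lenient selection, clustering and reporting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, norm, rankdata

from lesionmap import (
    derive_lenient_threshold,
    extract_clusters,
    fdr_select,
    inclusion_mask,
    lenient_select,
    map_scores,
    tabulate_structures,
    toy_atlas,
    voxel_test,
)
from lesionmap.vlsm import bh_reject, report_voxel, VlsmResult

from .conftest import make_cohort


# --- independent oracles -------------------------------------------------


def ranksum_u(x, y):
    """Brute-force U of x over y by pair counting (ties count half)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return gt + 0.5 * eq


def exact_permutation_p(x, y, mid=False):
    """One-sided p that the x-group ranks as low or lower, by enumeration.

    ``mid=True`` counts assignments tied with the observed statistic at half
    weight (the mid-p convention, the exact analogue of a normal
    approximation without continuity correction).
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    observed = ranksum_u(x, y)
    below = ties = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        u = ranksum_u(pooled[sel], pooled[~sel])
        below += u < observed - 1e-9
        ties += abs(u - observed) < 1e-9
        total += 1
    return (below + (0.5 if mid else 1.0) * ties) / total


def bh_oracle(p, q):
    """Literal step-up: sort, find largest i with p_(i) <= i q / m."""
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


# --- voxel_test ----------------------------------------------------------


class TestVoxelTest:
    def test_separated_groups(self):
        z, p = voxel_test([1, 2, 3], [4, 5, 6])
        # U = 0, mean 4.5, sd sqrt(5.25)
        assert z == pytest.approx(4.5 / np.sqrt(5.25), abs=1e-12)
        assert z == pytest.approx(1.964, abs=1e-3)
        exact = exact_permutation_p(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert exact == pytest.approx(0.05)
        assert p == pytest.approx(exact, abs=0.03)

    def test_degenerate_ties(self):
        assert voxel_test([5, 5, 5], [5, 5, 5]) == (0.0, 0.5)

    def test_group_swap_negates_z(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=5), rng.normal(size=7)
        z_xy, _ = voxel_test(x, y)
        z_yx, _ = voxel_test(y, x)
        assert z_xy == pytest.approx(-z_yx, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            voxel_test([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n in range(4, 11)
                                       for n1 in range(1, n) for n2 in [n - n1]])
    def test_matches_enumeration_small_n(self, n1, n2):
        """Rank-sum statistic exact vs pair counting; tail p near exact p.

        The statistic must agree exactly with the brute-force pair count for
        every split. The normal-approximation p is compared against the
        mid-p exhaustive enumeration: agreement to 0.03 holds in the
        decision-relevant tail (exact p <= 0.1); in mid-range p the discrete
        null at these group sizes deviates from the normal curve by up to
        ~0.07 whatever the convention, so only a coarser bound can hold
        there.
        """
        for rep in range(3):
            rng = np.random.default_rng(n1 * 1000 + n2 * 10 + rep)
            pooled = np.round(rng.normal(size=n1 + n2), 1)  # ties likely
            x, y = pooled[:n1], pooled[n1:]
            ranks = rankdata(pooled)
            u_from_ranks = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            assert u_from_ranks == pytest.approx(ranksum_u(x, y), abs=1e-9)
            z, p = voxel_test(x, y)
            if np.ptp(pooled) == 0:
                continue
            exact_mid = exact_permutation_p(x, y, mid=True)
            if exact_mid <= 0.1:
                assert p == pytest.approx(exact_mid, abs=0.03)
            assert p == pytest.approx(exact_mid, abs=0.08)

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = np.round(rng.normal(size=rng.integers(3, 15)), 1)
            y = np.round(rng.normal(size=rng.integers(3, 15)), 1)
            z, p = voxel_test(x, y)
            # scipy tests the alternative "x < y", matching z > 0 = worse
            ref = mannwhitneyu(
                x, y, alternative="less", method="asymptotic", use_continuity=False
            )
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_z_p_consistency(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=9), rng.normal(size=12)
        z, p = voxel_test(x, y)
        assert p == pytest.approx(norm.sf(z), abs=1e-12)


# --- inclusion -----------------------------------------------------------


class TestInclusionMask:
    def test_coverage_floor_41(self, default_cohort):
        cohort, _ = default_cohort
        assert cohort.n_subjects == 41
        _, min_lesioned = inclusion_mask(cohort, 0.20)
        assert min_lesioned == 8

    def test_coverage_floor_10(self, small_grid):
        lesions = [[(0, 0, 0)]] * 3 + [[]] * 7
        cohort = make_cohort(small_grid, lesions, list(range(10)))
        included, min_lesioned = inclusion_mask(cohort, 0.20)
        assert min_lesioned == 2
        assert included[0, 0, 0]

    def test_intact_guard(self, small_grid):
        # voxel lesioned in 40 of 41 subjects: only 1 intact -> untestable
        lesions = [[(5, 5, 5)]] * 40 + [[]]
        cohort = make_cohort(small_grid, lesions, list(range(41)))
        included, _ = inclusion_mask(cohort, 0.20)
        assert not included[5, 5, 5]

    def test_coverage_bounds(self, default_cohort):
        cohort, _ = default_cohort
        with pytest.raises(ValueError):
            inclusion_mask(cohort, 0.0)
        with pytest.raises(ValueError):
            inclusion_mask(cohort, 1.0)


# --- map_scores ----------------------------------------------------------


class TestMapScores:
    def test_single_voxel_composition(self, small_grid):
        lesions = [[(3, 3, 3)]] * 3 + [[]] * 3
        cohort = make_cohort(small_grid, lesions, [1, 2, 3, 4, 5, 6])
        inclusion = np.zeros(small_grid.dims, dtype=bool)
        inclusion[3, 3, 3] = True
        result = map_scores(cohort, "FMA_UL", inclusion)
        z_ref, p_ref = voxel_test([1, 2, 3], [4, 5, 6])
        assert result.z[3, 3, 3] == pytest.approx(z_ref, abs=1e-12)
        assert result.p[3, 3, 3] == pytest.approx(p_ref, abs=1e-12)
        assert np.isnan(result.z[0, 0, 0])

    def test_vectorized_matches_scalar(self, default_cohort):
        cohort, _ = default_cohort
        inclusion, _ = inclusion_mask(cohort)
        result = map_scores(cohort, "FMA_UL", inclusion)
        scores = cohort.score_vector("FMA_UL")
        lesions = cohort.lesion_matrix()
        rng = np.random.default_rng(0)
        flat = rng.choice(np.flatnonzero(inclusion.ravel()), 25, replace=False)
        for f in flat:
            les = lesions[:, f].astype(bool)
            z_ref, p_ref = voxel_test(scores[les], scores[~les])
            assert result.z.ravel()[f] == pytest.approx(z_ref, abs=1e-10)
            assert result.p.ravel()[f] == pytest.approx(p_ref, abs=1e-10)

    def test_type_i_error_rate(self, small_grid):
        """Scores independent of lesions: ~5% of voxels reach p < 0.05."""
        rng = np.random.default_rng(42)
        n, n_vox = 40, 500
        grid_dims = small_grid.dims
        lesion_sets = [
            np.argwhere(rng.random(grid_dims) < 0.4) for _ in range(n)
        ]
        cohort = make_cohort(small_grid, lesion_sets, rng.normal(size=n), score="NULL")
        counts = sum(m.data for m in cohort.masks)
        inclusion = (counts >= 8) & (counts <= n - 2)
        # ensure enough tested voxels for a stable rate
        inclusion_flat = np.flatnonzero(inclusion.ravel())[:n_vox]
        inc = np.zeros(grid_dims, dtype=bool)
        inc.ravel()[inclusion_flat] = True
        result = map_scores(cohort, "NULL", inc)
        pvals = result.p[inc]
        rate = (pvals < 0.05).mean()
        # 99% binomial envelope around 0.05 for m tested voxels (correlated
        # voxels inflate the variance; the envelope is generous)
        m = len(pvals)
        half = 3 * np.sqrt(0.05 * 0.95 / m)
        assert rate < 0.05 + 4 * half

    def test_planted_effect_peak_in_region(self, default_cohort):
        cohort, truth = default_cohort
        inclusion, _ = inclusion_mask(cohort)
        result = map_scores(cohort, "FMA_UL", inclusion)
        peak = np.unravel_index(np.nanargmax(result.z), result.z.shape)
        assert truth["region_a"][peak]


# --- selection -----------------------------------------------------------


def _result_from_p(p_values, grid):
    """Wrap a flat p vector into a VlsmResult on the first axis of a grid."""
    dims = grid.dims
    inclusion = np.zeros(dims, dtype=bool)
    inclusion.ravel()[: len(p_values)] = True
    p = np.full(dims, np.nan)
    p.ravel()[: len(p_values)] = p_values
    z = np.full(dims, np.nan)
    z.ravel()[: len(p_values)] = norm.isf(p_values)
    return VlsmResult(
        score_name="s", grid=grid, inclusion=inclusion, z=z, p=p,
        min_lesioned=0, n_subjects=0,
    )


class TestSelection:
    def test_bh_stepup_example(self, small_grid):
        result = _result_from_p(np.array([0.01, 0.02, 0.03, 0.5]), small_grid)
        out = fdr_select(result, q=0.05)
        assert out.n_significant == 3
        assert not out.sig.ravel()[3]
        assert out.threshold_info["p_star"] == pytest.approx(0.03)

    def test_all_ones_rejects_nothing(self, small_grid):
        out = fdr_select(_result_from_p(np.ones(20), small_grid), q=0.05)
        assert out.n_significant == 0
        assert np.isnan(out.threshold_info["p_star"])

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_q_monotonicity_and_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 200)) ** rng.uniform(0.5, 3)
        strict, _ = bh_reject(p, 0.01)
        loose, _ = bh_reject(p, 0.05)
        assert (strict <= loose).all()
        np.testing.assert_array_equal(loose, bh_oracle(p, 0.05))

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.random(rng.integers(2, 300))
            reject, _ = bh_reject(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(reject, ref)

    def test_lenient_correspondence(self, small_grid):
        rng = np.random.default_rng(2)
        result = _result_from_p(rng.random(200), small_grid)
        out = lenient_select(result, 2.09)
        assert out.threshold_info["p_star"] == pytest.approx(0.0183, abs=5e-4)
        selected_p = out.p[out.sig]
        assert (selected_p <= 0.0184).all()

    def test_lenient_extremes(self, small_grid):
        rng = np.random.default_rng(3)
        result = _result_from_p(rng.random(100), small_grid)
        assert lenient_select(result, np.inf).n_significant == 0
        everything = lenient_select(result, -np.inf)
        np.testing.assert_array_equal(everything.sig, result.inclusion)

    def test_fdr_never_beats_matched_lenient(self, small_grid):
        rng = np.random.default_rng(4)
        result = _result_from_p(rng.random(150) ** 2, small_grid)
        fdr = fdr_select(result, 0.05)
        if fdr.n_significant:
            matched = lenient_select(result, fdr.threshold_info["z_star"])
            assert fdr.n_significant <= matched.n_significant

    def test_derive_lenient_threshold(self, small_grid):
        result = _result_from_p(np.array([0.001, 0.004, 0.01, 0.9]), small_grid)
        out = fdr_select(result, 0.05)
        z_min = derive_lenient_threshold(out)
        assert z_min == pytest.approx(np.nanmin(out.z[out.sig]))
        # adding a larger-z (smaller-p) voxel cannot change the minimum
        result2 = _result_from_p(np.array([0.0001, 0.001, 0.004, 0.01, 0.9]), small_grid)
        out2 = fdr_select(result2, 0.05)
        assert derive_lenient_threshold(out2) == pytest.approx(z_min)

    def test_derive_requires_nonempty(self, small_grid):
        out = fdr_select(_result_from_p(np.ones(5), small_grid), 0.05)
        with pytest.raises(ValueError):
            derive_lenient_threshold(out)


# --- clusters ------------------------------------------------------------


def _sig_result(grid, sig, z=None):
    inclusion = np.ones(grid.dims, dtype=bool)
    z = np.where(sig, 3.0, 0.0) if z is None else z
    return VlsmResult(
        score_name="s", grid=grid, inclusion=inclusion, z=z,
        p=norm.sf(z), min_lesioned=0, n_subjects=0, sig=sig,
        threshold_info={"mode": "lenient"},
    )


class TestClusters:
    def test_size_filter(self, small_grid):
        sig = np.zeros(small_grid.dims, dtype=bool)
        sig[0, 0:6, 0:2] = True  # 12-voxel slab
        sig[5, 0:5, 5] = True  # 5-voxel line
        clusters = extract_clusters(_sig_result(small_grid, sig), min_size=10)
        assert len(clusters) == 1
        assert clusters[0].size == 12

    def test_empty(self, small_grid):
        sig = np.zeros(small_grid.dims, dtype=bool)
        assert extract_clusters(_sig_result(small_grid, sig)) == []

    def test_corner_touch_adjacency_switch(self, small_grid):
        sig = np.zeros(small_grid.dims, dtype=bool)
        sig[0:2, 0:2, 0:3] = True  # blob 1 (12 voxels)
        sig[2:4, 2:4, 3:6] = True  # blob 2, touches only at corner (2,2,3)
        res = _sig_result(small_grid, sig)
        assert len(extract_clusters(res, min_size=10, adjacency=26)) == 1
        assert len(extract_clusters(res, min_size=10, adjacency=6)) == 2

    def test_cluster_sizes_partition_sig(self, default_cohort):
        cohort, _ = default_cohort
        inclusion, ml = inclusion_mask(cohort)
        res = fdr_select(map_scores(cohort, "FMA_UL", inclusion, ml))
        clusters = extract_clusters(res, min_size=1)
        assert sum(c.size for c in clusters) == res.n_significant


class TestReportVoxel:
    def test_unique_max(self, small_grid):
        voxels = np.array([[1, 1, 1], [2, 2, 2]])
        idx, _ = report_voxel(voxels, np.array([1.0, 2.0]), small_grid)
        assert idx == (2, 2, 2)

    def test_superior_wins(self, small_grid):
        voxels = np.array([[3, 3, 2], [3, 3, 7]])  # world z = 2*k - 9
        idx, mm = report_voxel(voxels, np.array([2.0, 2.0]), small_grid)
        assert idx == (3, 3, 7)
        assert mm[2] > 0

    def test_then_posterior_then_left(self, small_grid):
        # tie in z (same k); world y = 2*j - 11 -> smaller j more posterior
        voxels = np.array([[3, 6, 4], [3, 2, 4]])
        idx, _ = report_voxel(voxels, np.array([2.0, 2.0]), small_grid)
        assert idx == (3, 2, 4)
        # tie in z and y; smaller i is more left (negative world x)
        voxels = np.array([[7, 3, 4], [2, 3, 4]])
        idx, _ = report_voxel(voxels, np.array([2.0, 2.0]), small_grid)
        assert idx == (2, 3, 4)


class TestTabulateStructures:
    def test_partition_across_structures(self, small_grid):
        sig = np.zeros(small_grid.dims, dtype=bool)
        sig[2:4, 2:5, 2:4] = True  # 12-voxel cluster
        rng = np.random.default_rng(0)
        z = np.where(sig, 2.0 + rng.random(small_grid.dims), 0.0)
        res = _sig_result(small_grid, sig, z)
        clusters = extract_clusters(res, min_size=10)
        atlas = toy_atlas(small_grid, (2, 1, 1))  # split along x at i=5
        table = tabulate_structures(res, clusters, atlas)
        assert table["n_voxels"].sum() == 12
        # fully inside the first block here
        assert len(table) == 1
        block_size = 5 * 12 * 10
        assert table.loc[0, "percent_area"] == pytest.approx(100 * 12 / block_size)

    def test_split_cluster_two_rows(self, small_grid):
        sig = np.zeros(small_grid.dims, dtype=bool)
        sig[3:7, 2, 2] = True
        sig[3:7, 3, 2] = True
        sig[3:7, 2, 3] = True  # 12 voxels spanning the i=5 atlas boundary
        res = _sig_result(small_grid, sig)
        clusters = extract_clusters(res, min_size=10)
        atlas = toy_atlas(small_grid, (2, 1, 1))
        table = tabulate_structures(res, clusters, atlas)
        assert len(table) == 2
        assert table["n_voxels"].sum() == 12

    def test_no_clusters_empty_table(self, small_grid):
        res = _sig_result(small_grid, np.zeros(small_grid.dims, dtype=bool))
        atlas = toy_atlas(small_grid, (2, 1, 1))
        assert len(tabulate_structures(res, [], atlas)) == 0
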