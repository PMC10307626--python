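import math

import numpy as np
import pytest
from scipy import stats

from ninjfil import (
    InvalidModelError,
    LocalizationTable,
    cluster_localizations,
    cluster_shape,
    compare_conditions,
    summarize_field,
)

from oracles import dbscan_brute_force


def _planted_field(rng, n_clusters=3, n_per=100, sigma=30.0, n_noise=50,
                   field_nm=10_000.0):
    centers = rng.uniform(2_000, field_nm - 2_000, (n_clusters, 2))
    # enforce >= 1 um separation
    while True:
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        d[np.diag_indices(n_clusters)] = np.inf
        if d.min() >= 1_000:
            break
        centers = rng.uniform(2_000, field_nm - 2_000, (n_clusters, 2))
    pts = [c + rng.normal(0, sigma, (n_per, 2)) for c in centers]
    noise = rng.uniform(0, field_nm, (n_noise, 2))
    xy = np.vstack(pts + [noise])
    return LocalizationTable.from_xy(xy), n_clusters, n_per, n_noise


class TestClusterLocalizations:
    def test_planted_gaussian_clusters_recovered(self, rng):
        locs, k, n_per, n_noise = _planted_field(rng)
        labels = cluster_localizations(locs, eps=100.0, min_pts=10)
        found = set(labels[labels >= 0].tolist())
        assert len(found) == k
        noise_frac = (labels == -1).mean()
        assert noise_frac == pytest.approx(n_noise / (k * n_per + n_noise), abs=0.03)

    def test_coincident_points_single_cluster(self):
        locs = LocalizationTable.from_xy(np.zeros((20, 2)))
        labels = cluster_localizations(locs, eps=10.0, min_pts=10)
        assert set(labels.tolist()) == {0}

    def test_empty_table(self):
        locs = LocalizationTable.from_xy(np.empty((0, 2)))
        assert len(cluster_localizations(locs, eps=10.0, min_pts=3)) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        xy = np.vstack(
            [
                rng.normal(rng.uniform(0, 500, 2), 20, (n // 2, 2)),
                rng.uniform(0, 600, (n - n // 2, 2)),
            ]
        )
        locs = LocalizationTable.from_xy(xy)
        mine = cluster_localizations(locs, eps=40.0, min_pts=5)
        oracle = dbscan_brute_force(xy, eps=40.0, min_pts=5)
        np.testing.assert_array_equal(mine, oracle)

    def test_noise_set_stable_under_permutation(self, rng):
        locs, *_ = _planted_field(rng)
        labels = cluster_localizations(locs, eps=100.0, min_pts=10)
        perm = rng.permutation(len(locs))
        permuted = LocalizationTable.from_xy(locs.xy[perm])
        labels_p = cluster_localizations(permuted, eps=100.0, min_pts=10)
        noise_original = set(np.flatnonzero(labels == -1).tolist())
        noise_permuted = {int(perm[i]) for i in np.flatnonzero(labels_p == -1)}
        assert noise_original == noise_permuted

    def test_invalid_parameters(self):
        locs = LocalizationTable.from_xy(np.zeros((3, 2)))
        with pytest.raises(InvalidModelError):
            cluster_localizations(locs, eps=-1.0, min_pts=3)
        with pytest.raises(InvalidModelError):
            cluster_localizations(locs, eps=1.0, min_pts=0)


class TestClusterShape:
    def test_square_is_isotropic(self):
        a = 7.0
        pts = np.array([[a, a], [a, -a], [-a, a], [-a, -a]])
        s = cluster_shape(pts)
        assert s.rg == pytest.approx(a * math.sqrt(2))
        assert s.ecc == pytest.approx(1.0)

    def test_anisotropic_gaussian_ecc(self, rng):
        sy = 25.0
        pts = rng.normal(0, 1, (10_000, 2)) * [3 * sy, sy]
        s = cluster_shape(pts)
        assert s.ecc == pytest.approx(3.0, rel=0.05)

    def test_collinear_flagged_with_sentinel(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        s = cluster_shape(pts)
        assert math.isinf(s.ecc)
        assert s.degenerate

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(InvalidModelError):
            cluster_shape(np.array([[1.0, 2.0]]))

    def test_rigid_motion_and_scaling_invariance(self, rng):
        pts = rng.normal(0, 1, (500, 2)) * [40.0, 15.0]
        base = cluster_shape(pts)
        theta = 1.1
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        moved = cluster_shape(pts @ rot.T + [1234.5, -987.6])
        assert moved.rg == pytest.approx(base.rg, rel=1e-9)
        assert moved.ecc == pytest.approx(base.ecc, rel=1e-9)
        scaled = cluster_shape(pts * 3.5)
        assert scaled.rg == pytest.approx(3.5 * base.rg, rel=1e-9)
        assert scaled.ecc == pytest.approx(base.ecc, rel=1e-9)

    def test_ecc_alternative_definition(self):
        pts = np.array([[2.0, 0.0], [-2.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        s = cluster_shape(pts)
        l1, l2 = s.eigenvalues
        assert s.ecc_alt() == pytest.approx(math.sqrt(1 - l2 / l1))


class TestSummarizeField:
    def test_density_from_planted_field(self, rng):
        locs, k, _, _ = _planted_field(rng, field_nm=10_000.0)  # 10x10 um
        labels = cluster_localizations(locs, eps=100.0, min_pts=10)
        summary = summarize_field(locs, labels, field_area_um2=100.0)
        assert summary.n_clusters == k
        assert summary.clusters_per_area_um2 == pytest.approx(k / 100.0)

    def test_zero_clusters(self):
        locs = LocalizationTable.from_xy(np.array([[0.0, 0.0], [5000.0, 5000.0]]))
        labels = np.array([-1, -1])
        summary = summarize_field(locs, labels, field_area_um2=50.0)
        assert summary.n_clusters == 0
        assert summary.clusters_per_area_um2 == 0.0
        assert summary.noise_fraction == 1.0

    def test_missing_area_keeps_counts(self, rng):
        locs, k, _, _ = _planted_field(rng)
        labels = cluster_localizations(locs, eps=100.0, min_pts=10)
        summary = summarize_field(locs, labels)
        assert summary.clusters_per_area_um2 is None
        assert summary.n_clusters == k

    def test_median_rg_recovers_planted_radius(self, rng):
        """Clusters sampled at known gyration radius: median within 3 SE."""
        sigma = 40.0  # isotropic Gaussian: Rg = sigma * sqrt(2)
        expected_rg = sigma * math.sqrt(2)
        rgs = []
        for _ in range(30):
            pts = rng.normal(0, sigma, (400, 2))
            rgs.append(cluster_shape(pts).rg)
        se = np.std(rgs, ddof=1) / math.sqrt(len(rgs))
        assert abs(np.median(rgs) - expected_rg) < 3 * se + 0.5


class TestCompareConditions:
    def test_identical_lists_give_null_result(self):
        res = compare_conditions([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_zero_variance_distinct_means(self):
        # hand evaluation of the two-sample t on (1,1,1) vs (2,2,2): s_p = 0
        res = compare_conditions([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert math.isinf(res.t)
        assert res.p == 0.0

    def test_matches_scipy_student_t(self, rng):
        a = rng.normal(10, 2, 6)
        b = rng.normal(12, 2, 5)
        res = compare_conditions(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_single_experiment_rejected(self):
        with pytest.raises(InvalidModelError, match="experiment"):
            compare_conditions([1.0], [2.0, 3.0])


class TestEccMonotonicity:
    def test_median_ecc_increases_with_elongation(self):
        """Median Ecc rises strictly across three planted elongation levels."""
        levels = (1.0, 2.0, 4.0)
        medians_by_level = []
        for stretch in levels:
            per_seed = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                eccs = [
                    cluster_shape(rng.normal(0, 30, (200, 2)) * [stretch, 1.0]).ecc
                    for _ in range(20)
                ]
                per_seed.append(np.median(eccs))
            medians_by_level.append(np.median(per_seed))
        assert medians_by_level[0] < medians_by_level[1] < medians_by_level[2]
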