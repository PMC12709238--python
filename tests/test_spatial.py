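import math

import numpy as np
import pytest
from scipy.stats import chisquare, mannwhitneyu

from isletkit.spatial import (
    community_neighborhood_contrast, concentric_partition,
    distance_binned_differences, hierarchical_clusters, mann_whitney_u,
    neighborhood_radius, overlap_proportion, subpopulation_by_region,
)


class TestDistanceBinnedDifferences:
    def test_constant_parameter_zero_profile(self, rng):
        pos = rng.uniform(0, 100, size=(40, 2))
        prof = distance_binned_differences(np.full(40, 0.7), pos, 10.0)
        occ = prof.n_pairs > 0
        assert np.allclose(prof.mean_abs_diff[occ], 0.0)

    def test_two_blobs(self, rng):
        # blob A at origin, blob B 200 um away; P = 0 vs 1
        a = rng.uniform(0, 20, size=(25, 2))
        b = rng.uniform(0, 20, size=(25, 2)) + [200.0, 0.0]
        pos = np.vstack([a, b])
        vals = np.array([0.0] * 25 + [1.0] * 25)
        prof = distance_binned_differences(vals, pos, 10.0, d_max_um=230.0)
        centers = prof.bin_centers
        short = (centers < 25) & (prof.n_pairs > 0)
        far = (centers > 180) & (centers < 220) & (prof.n_pairs > 0)
        assert np.all(prof.mean_abs_diff[short] == 0.0)
        assert np.all(prof.mean_abs_diff[far] == 1.0)

    def test_matches_bruteforce(self, rng):
        n = 50
        pos = rng.uniform(0, 150, size=(n, 2))
        vals = rng.normal(size=n)
        bw, dmax = 12.0, 160.0
        prof = distance_binned_differences(vals, pos, bw, d_max_um=dmax)
        n_bins = len(prof.n_pairs)
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        sq = np.zeros(n_bins)
        for i in range(n):
            for j in range(i + 1, n):
                d = math.hypot(*(pos[i] - pos[j]))
                k = int(d // bw)
                if k < n_bins:
                    dp = abs(vals[i] - vals[j])
                    sums[k] += dp
                    counts[k] += 1
                    sq[k] += dp * dp
        assert np.array_equal(prof.n_pairs, counts)
        occ = counts > 0
        np.testing.assert_allclose(prof.mean_abs_diff[occ], sums[occ] / counts[occ])
        multi = counts > 1
        sd = np.sqrt((sq[multi] - sums[multi] ** 2 / counts[multi])
                     / (counts[multi] - 1))
        np.testing.assert_allclose(prof.se[multi], sd / np.sqrt(counts[multi]),
                                   atol=1e-12)

    def test_empty_bins_are_nan(self):
        pos = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        prof = distance_binned_differences(np.arange(3.0), pos, 10.0,
                                           d_max_um=150.0)
        assert np.isnan(prof.mean_abs_diff[0])
        assert prof.n_pairs[0] == 0

    def test_rigid_motion_invariance(self, rng):
        pos = rng.uniform(0, 100, size=(30, 2))
        vals = rng.normal(size=30)
        prof = distance_binned_differences(vals, pos, 10.0, d_max_um=120.0)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        prof2 = distance_binned_differences(vals, pos @ rot.T + [55.0, -3.0],
                                            10.0, d_max_um=120.0)
        np.testing.assert_allclose(prof.mean_abs_diff, prof2.mean_abs_diff,
                                   equal_nan=True, atol=1e-9)


class TestNeighborhoodRadius:
    def test_square_lattice_formula(self):
        # interior cells: 4 neighbours at a, 2 at a*sqrt(2)
        a = 10.0
        xs, ys = np.meshgrid(np.arange(30), np.arange(30))
        pos = np.column_stack([xs.ravel(), ys.ravel()]) * a
        from scipy.spatial import cKDTree
        d, _ = cKDTree(pos).query(pos, k=7)
        per_cell = d[:, 1:].mean(axis=1)
        interior = ((xs.ravel() > 0) & (xs.ravel() < 29)
                    & (ys.ravel() > 0) & (ys.ravel() < 29))
        expect = (4 * a + 2 * a * math.sqrt(2)) / 6
        np.testing.assert_allclose(per_cell[interior], expect)
        # function value = 1.5 x mean over all cells (edges included)
        assert neighborhood_radius(pos) == pytest.approx(1.5 * per_cell.mean())

    def test_grid_mode_22(self, rng):
        assert neighborhood_radius(rng.uniform(0, 10, (20, 2)), "grid") == 22.0

    def test_scaling_homogeneity(self, rng):
        pos = rng.uniform(0, 100, size=(50, 2))
        assert neighborhood_radius(pos * 2) == pytest.approx(
            2 * neighborhood_radius(pos))

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            neighborhood_radius(np.zeros((5, 2)))


class TestNeighborhoodContrast:
    def test_single_community_diff_undefined(self, rng):
        pos = rng.uniform(0, 50, size=(20, 2))
        with pytest.warns(UserWarning):
            c = community_neighborhood_contrast(rng.random(20), pos,
                                                np.zeros(20, dtype=int), 30.0)
        assert np.all(np.isnan(c.diff_mean))

    def test_construction_same_zero_diff_positive(self):
        pos = np.column_stack([np.arange(20) * 10.0, np.zeros(20)])
        labels = np.array([0] * 10 + [1] * 10)
        vals = np.where(labels == 0, 0.2, 0.8)
        c = community_neighborhood_contrast(vals, pos, labels, 25.0)
        assert np.nanmax(c.same_mean) == 0.0
        assert np.nanmin(c.diff_mean) > 0.0
        assert c.p_value < 0.01


class TestHierarchicalClusters:
    def test_each_cell_own_cluster(self, rng):
        pos = rng.uniform(0, 100, size=(15, 2))
        labels = hierarchical_clusters(pos, n_clusters=15)
        assert len(np.unique(labels)) == 15

    def test_two_blobs_euclidean(self, rng):
        a = rng.uniform(0, 20, size=(12, 2))
        b = rng.uniform(0, 20, size=(12, 2)) + [300.0, 0.0]
        labels = hierarchical_clusters(np.vstack([a, b]), n_clusters=2)
        assert len(np.unique(labels[:12])) == 1
        assert len(np.unique(labels[12:])) == 1
        assert labels[0] != labels[12]

    def test_active_time_metric_separation(self, rng):
        pos = rng.uniform(0, 100, size=(20, 2))
        at = np.array([0.1] * 10 + [0.9] * 10)
        labels = hierarchical_clusters(pos, active_time=at,
                                       metric="active_time", n_clusters=2)
        assert len(np.unique(labels[:10])) == 1
        assert len(np.unique(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_n_clusters_bounds(self, rng):
        with pytest.raises(ValueError):
            hierarchical_clusters(rng.uniform(size=(5, 2)), n_clusters=6)


class TestOverlapProportion:
    def test_identical_partitions(self, rng):
        labels = rng.integers(0, 4, 60)
        res = overlap_proportion(labels, labels)
        assert res.proportion_matched == 1.0

    def test_random_two_labels_near_baseline(self):
        rng = np.random.default_rng(7)
        comms = np.array([0] * 30 + [1] * 30)
        clusters = rng.integers(0, 2, 60)
        res = overlap_proportion(comms, clusters, seed=1)
        assert abs(res.proportion_matched - res.baseline_random) \
            <= 3 * res.baseline_sd + 1e-9
        assert res.baseline_random == pytest.approx(0.5, abs=0.1)

    def test_hungarian_hand_example(self):
        comms = np.repeat([0, 1, 2], 10)
        clusters = comms.copy()
        clusters[[0, 10, 20]] = [1, 2, 0]  # relabel 3 cells
        res = overlap_proportion(comms, clusters)
        assert res.proportion_matched == pytest.approx(27 / 30)

    def test_relabeling_invariance(self, rng):
        labels = rng.integers(0, 3, 45)
        relabeled = (labels + 1) % 3
        assert overlap_proportion(labels, relabeled).proportion_matched == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            overlap_proportion(np.zeros(5), np.zeros(6))


class TestConcentricPartition:
    def test_eight_equal_areas(self, default_islet):
        ts, _ = default_islet
        rp = concentric_partition(ts.positions)
        assert len(rp.region_areas) == 8
        assert np.ptp(rp.region_areas) / rp.region_areas.mean() < 0.01
        assert set(np.unique(rp.region_label)) <= set(range(1, 9))

    def test_areas_sum_to_hull_area(self, default_islet):
        from scipy.spatial import ConvexHull
        ts, _ = default_islet
        rp = concentric_partition(ts.positions)
        assert rp.region_areas.sum() == pytest.approx(
            ConvexHull(ts.positions).volume)

    def test_centroid_cell_in_region_1(self):
        th = np.linspace(0, 2 * np.pi, 13)[:-1]
        pos = np.column_stack([np.cos(th), np.sin(th)]) * 100.0
        pos = np.vstack([pos, [[0.4, -0.2]]])  # near-centroid cell
        rp = concentric_partition(pos)
        assert rp.region_label[-1] == 1

    def test_hull_vertices_in_region_8(self, rng):
        pos = rng.uniform(-50, 50, size=(200, 2))
        from scipy.spatial import ConvexHull
        hull = ConvexHull(pos)
        rp = concentric_partition(pos)
        assert np.all(rp.region_label[hull.vertices] == 8)

    def test_uniform_disk_counts(self):
        # uniform field: expected N/8 cells per region (chi^2 at alpha=0.01)
        rng = np.random.default_rng(0)
        r = np.sqrt(rng.uniform(0, 1, 4000))
        th = rng.uniform(0, 2 * np.pi, 4000)
        pos = np.column_stack([r * np.cos(th), r * np.sin(th)]) * 200.0
        rp = concentric_partition(pos)
        counts = np.bincount(rp.region_label, minlength=9)[1:]
        assert chisquare(counts).pvalue > 0.01

    def test_degenerate_hull(self):
        pos = np.column_stack([np.arange(5.0), np.arange(5.0)])  # collinear
        with pytest.raises(ValueError, match="hull"):
            concentric_partition(pos)


class TestSubpopulationByRegion:
    def test_fractions_sum_to_one(self, default_islet):
        ts, gt = default_islet
        rp = concentric_partition(ts.positions)
        frac, _ = subpopulation_by_region(rp, gt.initiator_flag)
        assert frac.sum() == pytest.approx(1.0)

    def test_all_flagged_in_region8(self, rng):
        pos = rng.uniform(-50, 50, size=(100, 2))
        rp = concentric_partition(pos)
        flags = rp.region_label == 8
        frac, _ = subpopulation_by_region(rp, flags)
        np.testing.assert_allclose(frac, [0] * 7 + [1])

    def test_uniform_flags_match_cell_shares(self):
        rng = np.random.default_rng(3)
        r = np.sqrt(rng.uniform(0, 1, 3000))
        th = rng.uniform(0, 2 * np.pi, 3000)
        pos = np.column_stack([r * np.cos(th), r * np.sin(th)]) * 150.0
        rp = concentric_partition(pos)
        flags = rng.random(3000) < 0.3
        frac, enrich = subpopulation_by_region(rp, flags)
        shares = np.bincount(rp.region_label, minlength=9)[1:] / 3000
        assert np.max(np.abs(frac - shares)) < 0.05
        assert np.nanmax(np.abs(enrich - 1)) < 0.35

    def test_no_flags_error(self, default_islet):
        ts, _ = default_islet
        rp = concentric_partition(ts.positions)
        with pytest.raises(ValueError):
            subpopulation_by_region(rp, np.zeros(100, dtype=bool))


class TestMannWhitneyU:
    def test_complete_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=0.01)  # exact: 2/20

    def test_identical_samples(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_matches_scipy_exact(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=7)
        u, p = mann_whitney_u(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matches_scipy_asymptotic(self, rng):
        a = rng.normal(size=25)
        b = rng.normal(0.5, 1.0, size=30)
        u, p = mann_whitney_u(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_type_one_error_calibration(self):
        # 300-rep smoke version; the full 1000-rep check runs in acceptance
        rng = np.random.default_rng(5)
        rej = sum(mann_whitney_u(rng.normal(size=20), rng.normal(size=20))[1] < 0.05
                  for _ in range(300))
        assert 0.01 <= rej / 300 <= 0.09
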