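"""Voxel-wise two-sample t-maps and cluster-extent thresholding."""

import numpy as np
import pytest
from scipy import stats

import petslice as ps
from conftest import flood_fill_components


def seeded_data(n=40, dims=(12, 12, 12), effect=0.5, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, *dims))
    region = np.zeros(dims, dtype=bool)
    region[3:7, 3:7, 3:7] = True
    for i in np.flatnonzero(y == 1):
        X[i][region] += effect
    return X, y, region


class TestVoxelwiseTTest:
    def test_single_voxel_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.3, 1.0, 12)
        b = rng.normal(0.0, 1.0, 10)
        X = np.concatenate([a, b]).reshape(-1, 1, 1, 1)
        y = np.array([1] * 12 + [0] * 10)
        sm = ps.voxelwise_ttest(X, y, equal_var=True)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert sm.t_map[0, 0, 0] == pytest.approx(t_ref, rel=1e-10)
        assert sm.p_map[0, 0, 0] == pytest.approx(p_ref, rel=1e-10)
        assert sm.df == 20

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3, 3, 3))
        y = np.repeat([0, 1], 15)
        sm = ps.voxelwise_ttest(X, y, equal_var=False)
        t_ref, p_ref = stats.ttest_ind(X[y == 1], X[y == 0], axis=0, equal_var=False)
        np.testing.assert_allclose(sm.t_map, t_ref, rtol=1e-10)
        np.testing.assert_allclose(sm.p_map, p_ref, rtol=1e-10)

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 10, 10, 10))
        y = rng.permutation(np.repeat([0, 1], 30))
        sm = ps.voxelwise_ttest(X, y)
        rate = float((sm.p_map[sm.mask] < 0.05).mean())
        assert 0.03 < rate < 0.07

    def test_label_negation_negates_t_map(self):
        X, y, _ = seeded_data(seed=4)
        a = ps.voxelwise_ttest(X, y)
        b = ps.voxelwise_ttest(X, 1 - y)
        np.testing.assert_allclose(a.t_map, -b.t_map, rtol=1e-10)

    def test_seeded_region_concentrates_signal(self):
        X, y, region = seeded_data(n=60, effect=1.0, seed=5)
        sm = ps.voxelwise_ttest(X, y)
        supra = sm.p_map < 0.001
        assert supra[region].mean() > 0.5
        assert supra[~region].mean() < 0.02

    def test_small_class_fails(self):
        X = np.zeros((4, 3, 3, 3))
        with pytest.raises(ValueError, match=">= 2 subjects"):
            ps.voxelwise_ttest(X, np.array([0, 0, 0, 1]))

    def test_zero_variance_voxels_dropped_from_mask(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 4, 4, 4))
        X[:, 0, 0, 0] = 1.0  # constant everywhere
        y = np.repeat([0, 1], 10)
        sm = ps.voxelwise_ttest(X, y)
        assert sm.n_zero_variance == 1
        assert not sm.mask[0, 0, 0]
        assert np.isnan(sm.t_map[0, 0, 0])


class TestThresholdAndCluster:
    def test_empty_suprathreshold_set(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 6, 6, 6))
        y = np.repeat([0, 1], 10)
        sm = ps.voxelwise_ttest(X, y)
        cr = ps.threshold_and_cluster(sm, p_threshold=1e-12)
        assert cr.clusters == []

    def test_extent_threshold_is_strict(self):
        # build a stat map by hand: one component of exactly 50, one of 51
        dims = (20, 20, 5)
        t = np.zeros(dims)
        p = np.ones(dims)
        m50 = np.zeros(dims, dtype=bool)
        m50[0:2, 0:5, 0:5] = True  # 50 voxels
        m51 = np.zeros(dims, dtype=bool)
        m51[10:12, 10:15, 0:5] = True
        m51[12, 10, 0] = True  # 51 voxels (18-connected to the block)
        for m in (m50, m51):
            t[m] = 5.0
            p[m] = 1e-6
        sm = ps.StatMap(t_map=t, p_map=p, df=30, mask=np.ones(dims, dtype=bool))
        cr = ps.threshold_and_cluster(sm, p_threshold=0.001, k=50)
        assert [c.size for c in cr.clusters] == [51]

    def test_components_match_flood_fill_oracle(self):
        X, y, _ = seeded_data(n=60, effect=0.8, seed=8)
        sm = ps.voxelwise_ttest(X, y)
        cr = ps.threshold_and_cluster(sm, p_threshold=0.01, k=0, connectivity=18)
        binary_pos = sm.mask & (sm.p_map < 0.01) & (sm.t_map > 0)
        binary_neg = sm.mask & (sm.p_map < 0.01) & (sm.t_map < 0)
        oracle = flood_fill_components(binary_pos, 18) + flood_fill_components(binary_neg, 18)
        ours = [frozenset(map(tuple, c.voxels)) for c in cr.clusters]
        assert sorted(ours, key=sorted) == sorted(oracle, key=sorted)
        assert cr.total_voxels == int(binary_pos.sum() + binary_neg.sum())

    def test_signs_partition_clusters(self):
        X, y, region = seeded_data(n=60, effect=1.0, seed=9)
        # add a negative-effect region
        neg_region = np.zeros(X.shape[1:], dtype=bool)
        neg_region[8:11, 8:11, 8:11] = True
        for i in np.flatnonzero(y == 1):
            X[i][neg_region] -= 1.5
        sm = ps.voxelwise_ttest(X, y)
        cr = ps.threshold_and_cluster(sm, p_threshold=0.001, k=5)
        signs = {c.sign for c in cr.clusters}
        assert signs == {1, -1}

    def test_unknown_correction_fails(self):
        dims = (4, 4, 4)
        sm = ps.StatMap(np.zeros(dims), np.ones(dims), 10, np.ones(dims, dtype=bool))
        with pytest.raises(ValueError, match="unknown correction"):
            ps.threshold_and_cluster(sm, correction="rft")

    def test_bonferroni_is_more_conservative(self):
        X, y, _ = seeded_data(n=60, effect=0.6, seed=10)
        sm = ps.voxelwise_ttest(X, y)
        raw = ps.threshold_and_cluster(sm, 0.01, "none", k=0)
        bonf = ps.threshold_and_cluster(sm, 0.01, "bonferroni", k=0)
        assert bonf.total_voxels <= raw.total_voxels

    def test_permutation_fwe_controls_error_and_detects_signal(self):
        X, y, region = seeded_data(n=60, effect=1.2, seed=11)
        sm = ps.voxelwise_ttest(X, y, fwe_permutations=200, seed=0)
        cr = ps.threshold_and_cluster(sm, 0.05, "fwe_perm", k=0)
        vox = np.zeros(X.shape[1:], dtype=bool)
        for c in cr.clusters:
            vox[tuple(c.voxels.T)] = True
        assert vox[region].sum() > 0          # signal found
        assert vox[~region].mean() < 0.01     # few familywise false positives

    def test_estimator_wrapper_exposes_fitted_maps(self):
        X, y, _ = seeded_data(seed=12)
        est = ps.VoxelwiseTTest().fit(X, y)
        np.testing.assert_allclose(est.t_map_, ps.voxelwise_ttest(X, y).t_map,
                                   rtol=1e-12)
        assert est.clusters(0.01, k=0).total_voxels >= 0
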