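"""Submodule-significance interpretation: t-test slice selection,
Cartesian point clouds, and per-ROI point tallies."""

import numpy as np
import pytest
from scipy import stats

import petslice as ps
from petslice.model import PredictionRecord


def make_records(P, predicted):
    return [
        PredictionRecord(f"s{i}", 0.5, P[i], int(predicted[i]))
        for i in range(len(P))
    ]


class TestSubmoduleSignificance:
    COUNTS = (6, 7, 5)

    def test_null_distributions_yield_near_alpha_rate(self):
        rng = np.random.default_rng(0)
        n, total = 400, sum(self.COUNTS)
        P = rng.uniform(size=(n, total))
        predicted = np.repeat([0, 1], n // 2)
        sx, sy, sz = ps.submodule_significance(make_records(P, predicted), self.COUNTS)
        rate = (len(sx) + len(sy) + len(sz)) / total
        assert rate <= 0.25  # small count expected at alpha=0.05 over 18 tests

    def test_injected_shift_detected_and_matches_direct_t(self):
        rng = np.random.default_rng(1)
        n, total = 60, sum(self.COUNTS)
        P = rng.normal(0.5, 0.05, size=(n, total))
        predicted = np.repeat([0, 1], n // 2)
        shifted = [2, 9, 17]  # one slice per axis
        for col in shifted:
            P[predicted == 1, col] += 0.3
        records = make_records(P, predicted)
        sx, sy, sz = ps.submodule_significance(records, self.COUNTS)
        got = {*(i for i in sx), *(i + 6 for i in sy), *(i + 13 for i in sz)}
        assert set(shifted) <= got
        # every reported slice agrees with a direct Welch t computation
        for col in got:
            t, p = stats.ttest_ind(P[predicted == 1, col], P[predicted == 0, col],
                                   equal_var=False)
            assert p < 0.05

    def test_zero_variance_submodule_excluded(self):
        rng = np.random.default_rng(2)
        n = 40
        P = rng.normal(0.5, 0.05, size=(n, sum(self.COUNTS)))
        P[:, 4] = 0.5  # constant in both groups
        predicted = np.repeat([0, 1], n // 2)
        sx, _, _ = ps.submodule_significance(make_records(P, predicted), self.COUNTS)
        assert 4 not in sx

    def test_small_predicted_class_fails(self):
        rng = np.random.default_rng(3)
        P = rng.uniform(size=(5, sum(self.COUNTS)))
        predicted = [0, 0, 0, 0, 1]
        with pytest.raises(ValueError, match="class 1"):
            ps.submodule_significance(make_records(P, predicted), self.COUNTS)

    def test_label_permutation_breaks_significance(self):
        # seeded shifts become undetectable when predictions are shuffled
        rng = np.random.default_rng(4)
        n, total = 200, sum(self.COUNTS)
        P = rng.normal(0.5, 0.05, size=(n, total))
        predicted = np.repeat([0, 1], n // 2)
        P[predicted == 1, :5] += 0.3
        rates = []
        for rep in range(20):
            perm = rng.permutation(predicted)
            sx, sy, sz = ps.submodule_significance(make_records(P, perm), self.COUNTS)
            rates.append((len(sx) + len(sy) + len(sz)) / total)
        assert np.mean(rates) < 0.15  # ~= alpha on average


class TestCartesianPoints:
    def test_worked_example_twelve_points(self):
        pts = ps.cartesian_points({46, 51}, {34, 64, 66}, {37, 45})
        assert len(pts) == 12
        assert [46, 34, 37] in pts.tolist() and [51, 66, 45] in pts.tolist()

    def test_two_slices_per_axis_gives_eight(self):
        pts = ps.cartesian_points({1, 2}, {3, 4}, {5, 6})
        assert len(pts) == 8

    def test_discussion_scale_product(self):
        pts = ps.cartesian_points(range(20), range(27), range(24))
        assert len(pts) == 20 * 27 * 24 == 12960

    def test_empty_axis_gives_empty_cloud(self):
        assert len(ps.cartesian_points(set(), {1}, {2})) == 0


class TestRoiClusters:
    def test_counts_match_brute_force_tally(self, toy_atlas):
        rng = np.random.default_rng(5)
        dims = toy_atlas.dims
        pts = np.column_stack([rng.integers(0, d, size=500) for d in dims])
        surviving, counts, background = ps.extract_roi_clusters(pts, toy_atlas, min_points=10)
        # independent per-point tally
        expect: dict = {}
        bg = 0
        for x, y, z in pts:
            lab = int(toy_atlas.labels[x, y, z])
            if lab == 0:
                bg += 1
            else:
                name = toy_atlas.name_of(lab)
                expect[name] = expect.get(name, 0) + 1
        assert counts == expect
        assert background == bg
        assert sum(counts.values()) + background == len(pts)
        for name, c in surviving:
            assert c > 10

    def test_strictly_more_than_threshold(self, toy_atlas):
        rid = int(toy_atlas.region_ids[0])
        vox = np.argwhere(toy_atlas.labels == rid)
        name = toy_atlas.name_of(rid)
        surviving, _, _ = ps.extract_roi_clusters(vox[:50], toy_atlas, min_points=50)
        assert name not in dict(surviving)
        surviving, _, _ = ps.extract_roi_clusters(vox[:51], toy_atlas, min_points=50)
        assert dict(surviving)[name] == 51

    def test_background_points_excluded(self, toy_atlas):
        bg_vox = np.argwhere(toy_atlas.labels == 0)[:100]
        surviving, counts, background = ps.extract_roi_clusters(bg_vox, toy_atlas, min_points=1)
        assert surviving == [] and counts == {} and background == 100

    def test_out_of_bounds_point_fails(self, toy_atlas):
        with pytest.raises(ValueError, match="outside"):
            ps.extract_roi_clusters(np.array([[999, 0, 0]]), toy_atlas)

    def test_connected_mode_respects_size_threshold(self, toy_atlas):
        rid = int(toy_atlas.region_ids[0])
        vox = np.argwhere(toy_atlas.labels == rid)
        surviving, _, _ = ps.extract_roi_clusters(vox, toy_atlas, min_points=10,
                                                  mode="connected")
        assert len(surviving) == 1
        assert surviving[0][0] == toy_atlas.name_of(rid)
        assert surviving[0][1] == len(vox)


class TestEndToEndRecovery:
    def test_seeded_region_survives(self, trained_classifier, normalized_stack,
                                    fdg_cohort, toy_atlas):
        """A trained model's interpretation recovers the discriminative regions."""
        records = trained_classifier.predict_record(normalized_stack)
        res = ps.interpret_predictions(records, toy_atlas,
                                       slice_counts=toy_atlas.dims,
                                       alpha=0.05, min_points=20)
        assert len(res.points) == len(res.sig_x) * len(res.sig_y) * len(res.sig_z)
        seeded = {"region_01", "region_02", "region_03"}
        assert seeded & {name for name, _ in res.surviving_rois}
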