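"""Synthetic atlas and cohort generators: construction guarantees,
determinism, prevalence control, and statistical calibration."""

import numpy as np
import pytest
from scipy import stats

import petslice as ps
from petslice.synthetic import SyntheticCohortConfig


class TestToyAtlas:
    def test_requested_regions_present_and_large_enough(self):
        atlas = ps.generate_toy_atlas((24, 28, 24), 6, seed=0)
        assert len(atlas.regions) == 8  # 6 cortical + pons + cerebellum
        assert set(atlas.regions["name"]) >= {"pons", "cerebellum"}
        for rid in atlas.region_ids:
            assert (atlas.labels == rid).sum() >= 60
        assert atlas.regions.loc[atlas.regions["name"] == "pons", "is_reference"].all()

    def test_template_scale_atlas(self):
        atlas = ps.generate_toy_atlas((91, 109, 91), 90, seed=0)
        assert len(atlas.regions) == 92
        for rid in atlas.region_ids:
            assert (atlas.labels == rid).sum() >= 60

    def test_too_small_volume_fails_with_capacity_message(self):
        with pytest.raises(ValueError, match="fit only"):
            ps.generate_toy_atlas((8, 8, 8), 50, seed=0)

    def test_dims_below_minimum_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            ps.generate_toy_atlas((4, 24, 24), 2, seed=0)


class TestConfigValidation:
    def test_overlapping_effect_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SyntheticCohortConfig(dims=(24, 28, 24), n_subjects=10,
                                  hypo_regions=[1, 2], hyper_regions=[2])

    @pytest.mark.parametrize("kw", [
        {"prevalence": 1.5}, {"effect_size": -0.1}, {"noise_sd": -1.0},
    ])
    def test_out_of_range_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(dims=(24, 28, 24), n_subjects=10, **kw)

    def test_unknown_region_ids_rejected(self, toy_atlas):
        cfg = SyntheticCohortConfig(dims=(24, 28, 24), n_subjects=10,
                                    hypo_regions=[99])
        with pytest.raises(ValueError, match="not in atlas"):
            ps.generate_cohort(cfg, toy_atlas)


class TestCohortGeneration:
    def test_exact_prevalence_half_of_100(self, toy_atlas):
        cfg = SyntheticCohortConfig(dims=(24, 28, 24), n_subjects=100,
                                    prevalence=0.5, seed=3)
        cohort = ps.generate_cohort(cfg, toy_atlas)
        assert int(cohort.labels.sum()) == 50

    def test_exact_prevalence_34_of_100_amyloid(self, toy_atlas):
        cfg = SyntheticCohortConfig(dims=(24, 28, 24), n_subjects=100,
                                    prevalence=0.34, seed=3,
                                    smooth_fwhm_vox=0.0)
        cohort = ps.generate_amyloid_cohort(cfg, toy_atlas)
        assert int(cohort.labels.sum()) == 34

    def test_degenerate_exact_prevalence_fails(self, toy_atlas):
        cfg = SyntheticCohortConfig(dims=(24, 28, 24), n_subjects=10,
                                    prevalence=0.01, seed=3)
        with pytest.raises(ValueError, match="zero"):
            ps.generate_cohort(cfg, toy_atlas)

    def test_fixed_seed_is_bit_identical(self, toy_atlas):
        cfg = SyntheticCohortConfig(dims=(24, 28, 24), n_subjects=8,
                                    hypo_regions=[1], seed=11)
        a = ps.generate_cohort(cfg, toy_atlas)
        b = ps.generate_cohort(cfg, toy_atlas)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.subgroups, b.subgroups)
        for va, vb in zip(a.volumes, b.volumes):
            np.testing.assert_array_equal(va.data, vb.data)

    def test_effect_direction_and_symmetry(self, toy_atlas):
        base = dict(dims=(24, 28, 24), n_subjects=80, effect_size=0.2,
                    noise_sd=0.02, smooth_fwhm_vox=0.0, seed=5)
        cfg = SyntheticCohortConfig(hypo_regions=[1], hyper_regions=[2], **base)
        swapped = SyntheticCohortConfig(hypo_regions=[2], hyper_regions=[1], **base)
        r1, r2 = toy_atlas.mask("region_01"), toy_atlas.mask("region_02")

        def group_diff(cohort, mask):
            norm = ps.ReferenceRegionNormalizer(atlas=toy_atlas).fit(None)
            X = norm.transform(cohort.stack())
            vals = X[:, mask].mean(axis=1)
            return vals[cohort.labels == 1].mean() - vals[cohort.labels == 0].mean()

        a, b = ps.generate_cohort(cfg, toy_atlas), ps.generate_cohort(swapped, toy_atlas)
        # hypo region is lower in positives; swapping the lists flips the sign
        assert group_diff(a, r1) < 0 < group_diff(a, r2)
        assert group_diff(b, r1) > 0 > group_diff(b, r2)
        assert group_diff(a, r1) == pytest.approx(group_diff(b, r2), abs=0.02)

    def test_null_effect_calibrates_to_alpha(self, toy_atlas):
        cfg = SyntheticCohortConfig(dims=(24, 28, 24), n_subjects=60,
                                    effect_size=0.0, noise_sd=0.05,
                                    smooth_fwhm_vox=0.0, seed=13)
        cohort = ps.generate_cohort(cfg, toy_atlas)
        # normalize first: the subject-level global scale couples all voxels,
        # so the raw map behaves like a single correlated test
        X = ps.ReferenceRegionNormalizer(atlas=toy_atlas).fit(None).transform(
            cohort.stack())
        mask = toy_atlas.brain_mask()
        vals = X[:, mask]
        t, p = stats.ttest_ind(vals[cohort.labels == 1], vals[cohort.labels == 0], axis=0)
        rate = float((p < 0.05).mean())
        assert 0.02 < rate < 0.10  # ~= alpha under the null

    def test_seeded_effect_detected_at_scale(self, toy_atlas):
        # strong effect, modest noise: most hypo-region voxels significant
        cfg = SyntheticCohortConfig(dims=(24, 28, 24), n_subjects=200,
                                    hypo_regions=[1, 2], effect_size=0.15,
                                    noise_sd=0.05, smooth_fwhm_vox=0.0, seed=17)
        cohort = ps.generate_cohort(cfg, toy_atlas)
        norm = ps.ReferenceRegionNormalizer(atlas=toy_atlas).fit(None)
        X = norm.transform(cohort.stack())
        hypo = np.isin(toy_atlas.labels, [1, 2])
        vals = X[:, hypo]
        t, p = stats.ttest_ind(vals[cohort.labels == 1], vals[cohort.labels == 0], axis=0)
        assert float((p < 0.001).mean()) > 0.5


class TestAmyloidCohort:
    def test_labels_recovered_with_margin(self, toy_atlas, amyloid_cohort):
        rois = [f"region_{i:02d}" for i in range(1, 5)]
        rule = ps.pib_rule(rois)
        df = ps.label_cohort(amyloid_cohort.volumes, toy_atlas, rule)
        assert np.array_equal(df["status"].to_numpy(), amyloid_cohort.labels)
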