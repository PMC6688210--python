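"""QC cascade: overlap restriction, quality filter, imputation, sample QC."""

import numpy as np
import pandas as pd
import pytest

from methylancestry.io import BetaMatrix
from methylancestry.preprocess import (
    PreprocessConfig,
    filter_poor_quality_sites,
    impute_knn,
    infer_sex,
    interarray_correlation_filter,
    remove_flagged_sites,
    restrict_to_platform_overlap,
    run_preprocess,
    sex_concordance_filter,
)
from methylancestry.simulate import SimulationConfig, simulate_cohorts

from conftest import make_annotation, make_beta, make_sheet


class TestPlatformOverlap:
    def test_off_platform_sites_dropped(self):
        bm = make_beta(np.full((10, 3), 0.5))
        ann = make_annotation(bm.site_ids, on_epic=[False] * 4 + [True] * 6)
        out, report = restrict_to_platform_overlap(bm, ann)
        assert out.n_sites == 6
        assert report.n_sites_removed == 4

    def test_all_on_platform_is_identity(self):
        bm = make_beta(np.full((5, 2), 0.5))
        out, report = restrict_to_platform_overlap(bm, make_annotation(bm.site_ids))
        assert list(out.site_ids) == list(bm.site_ids)
        assert report.n_sites_removed == 0

    def test_snp_probes_survive_overlap(self, default_sim):
        _, bm, _, ann, truth = default_sim
        out, _ = restrict_to_platform_overlap(bm, ann)
        snp_sites = truth.sites.loc[truth.sites["role"] == "snp_probe", "site_id"]
        assert len(snp_sites) == 59
        assert set(snp_sites).issubset(set(out.site_ids))

    def test_unannotated_site_errors(self):
        bm = make_beta(np.full((3, 2), 0.5))
        ann = make_annotation(list(bm.site_ids[:2]))
        with pytest.raises(ValueError, match="unannotated"):
            restrict_to_platform_overlap(bm, ann)


class TestQualityFilter:
    def test_strictly_greater_than_one_percent_rule(self):
        # 100 samples: 2 failures (2%) removed, exactly 1 failure (1%) kept
        beta = np.full((2, 100), 0.5)
        det = np.zeros((2, 100))
        det[0, :2] = 0.5
        det[1, :1] = 0.5
        bm = make_beta(beta, detection_p=det)
        out, report = filter_poor_quality_sites(bm)
        assert report.sites_removed == ["cg000"]
        assert out.n_sites == 1
        # surviving failure masked for imputation
        assert np.isnan(out.beta.iloc[0, 0])

    def test_boundary_bead_count_three_does_not_fail(self):
        bm = make_beta(
            np.full((3, 10), 0.5),
            detection_p=np.zeros((3, 10)),
            bead_count=np.full((3, 10), 3.0),
        )
        out, report = filter_poor_quality_sites(bm)
        assert report.n_sites_removed == 0
        assert not out.beta.isna().any().any()

    def test_planted_defect_sites_exactly_recovered(self, tiny_sim):
        _, bm, _, _, truth = tiny_sim
        _, report = filter_poor_quality_sites(bm)
        planted = truth.sites.loc[
            truth.sites["planted_failed_detection"] | truth.sites["planted_low_bead"],
            "site_id",
        ]
        assert set(report.sites_removed) == set(planted)
        assert report.n_sites_removed == 7 + 5

    def test_no_layers_is_noop_with_warning(self, caplog):
        bm = make_beta(np.full((2, 5), 0.5))
        out, report = filter_poor_quality_sites(bm)
        assert out.n_sites == 2 and report.n_sites_removed == 0


class TestKnnImputation:
    def test_no_missing_is_identity(self):
        bm = make_beta(np.random.default_rng(0).uniform(size=(5, 4)))
        out = impute_knn(bm, k=2)
        assert (out.beta.to_numpy() == bm.beta.to_numpy()).all()

    def test_nearest_site_value_used_for_k1(self):
        vals = np.array(
            [
                [0.10, 0.20, np.nan],
                [0.10, 0.20, 0.40],
                [0.90, 0.90, 0.90],
            ]
        )
        out = impute_knn(make_beta(vals), k=1)
        assert out.beta.iloc[0, 2] == pytest.approx(0.40)
        # observed values untouched
        assert (out.beta.to_numpy()[~np.isnan(vals)] == vals[~np.isnan(vals)]).all()

    def test_k_larger_than_sites_clamped(self):
        vals = np.array([[0.1, np.nan], [0.2, 0.3], [0.3, 0.5]])
        out = impute_knn(make_beta(vals), k=50)
        assert out.beta.iloc[0, 1] == pytest.approx((0.3 + 0.5) / 2)

    def test_all_missing_site_errors(self):
        vals = np.array([[np.nan, np.nan], [0.2, 0.3]])
        with pytest.raises(ValueError, match="no observed values"):
            impute_knn(make_beta(vals))


class TestFlaggedSites:
    def test_disjoint_flags_counted(self):
        bm = make_beta(np.full((10, 2), 0.5))
        ann = make_annotation(
            bm.site_ids,
            cross_hybridizing=[True] * 5 + [False] * 5,
            nonvariable=[False] * 5 + [True] * 3 + [False] * 2,
        )
        _, report = remove_flagged_sites(bm, ann)
        assert report.n_sites_removed == 8

    def test_overlapping_flags_counted_once(self):
        bm = make_beta(np.full((4, 2), 0.5))
        ann = make_annotation(
            bm.site_ids,
            cross_hybridizing=[True, True, False, False],
            nonvariable=[True, False, True, False],
        )
        out, report = remove_flagged_sites(bm, ann)
        assert report.n_sites_removed == 3
        assert out.n_sites == 1

    def test_snp_probes_exempt_from_nonvariable(self):
        bm = make_beta(np.full((2, 2), 0.5))
        ann = make_annotation(
            bm.site_ids, probe_class=["SNP", "CpG"], nonvariable=[True, True]
        )
        out, report = remove_flagged_sites(bm, ann)
        assert list(out.site_ids) == [bm.site_ids[0]]

    def test_planted_flag_sets_recovered(self, tiny_sim):
        _, bm, _, ann, truth = tiny_sim
        _, report = remove_flagged_sites(bm, ann)
        planted = truth.sites.loc[
            truth.sites["role"].isin(["crosshyb", "nonvariable"]), "site_id"
        ]
        assert set(report.sites_removed) == set(planted)


class TestSexInference:
    def _sex_fixture(self, rng, flip=None):
        n = 20
        sex = np.array(["M"] * 10 + ["F"] * 10)
        y = np.where(sex == "M", 0.8, 0.1) + rng.normal(0, 0.03, size=(15, n))
        x = np.where(sex == "M", 0.8, 0.5) + rng.normal(0, 0.03, size=(15, n))
        bm = make_beta(np.clip(np.vstack([y, x]), 0, 1))
        ann = make_annotation(bm.site_ids, chromosome=["Y"] * 15 + ["X"] * 15)
        reported = sex.copy()
        if flip is not None:
            reported[flip] = "F" if reported[flip] == "M" else "M"
        sheet = make_sheet(bm.sample_ids, reported_sex=list(reported))
        return bm, ann, sheet, sex

    def test_clear_separation_gives_full_concordance(self):
        bm, ann, sheet, sex = self._sex_fixture(np.random.default_rng(1))
        table = infer_sex(bm, ann, sheet)
        assert (table["inferred_sex"].to_numpy() == sex).all()
        assert table["concordant"].all()

    def test_planted_mislabel_flagged(self):
        bm, ann, sheet, _ = self._sex_fixture(np.random.default_rng(2), flip=3)
        out, table, report = sex_concordance_filter(bm, ann, sheet)
        assert report.samples_removed == [bm.sample_ids[3]]
        assert out.n_samples == 19

    def test_single_sex_cohort_degenerate_warns(self, caplog):
        rng = np.random.default_rng(3)
        vals = np.clip(0.8 + rng.normal(0, 0.01, size=(6, 8)), 0, 1)
        bm = make_beta(vals)
        ann = make_annotation(bm.site_ids, chromosome=["Y"] * 3 + ["X"] * 3)
        table = infer_sex(bm, ann)
        # clustering still cuts at 2, but with no real structure we only
        # require the function to return a label per sample
        assert len(table) == 8

    def test_too_few_sex_sites_errors(self):
        bm = make_beta(np.full((3, 4), 0.5))
        ann = make_annotation(bm.site_ids, chromosome=["Y", "1", "2"])
        with pytest.raises(ValueError, match="sex-chromosome sites"):
            infer_sex(bm, ann)


class TestInterarrayCorrelation:
    def test_noise_sample_removed(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0.05, 0.95, size=200)
        good = base[:, None] + rng.normal(0, 0.01, size=(200, 6))
        noise = rng.uniform(size=(200, 1))
        bm = make_beta(np.clip(np.hstack([good, noise]), 0, 1))
        out, mean_r, report = interarray_correlation_filter(bm)
        assert report.samples_removed == ["S6"]
        assert mean_r["S6"] < 0.3
        assert out.n_samples == 6

    def test_identical_samples_all_kept(self):
        col = np.linspace(0.1, 0.9, 50)
        bm = make_beta(np.tile(col[:, None], (1, 4)))
        out, mean_r, report = interarray_correlation_filter(bm)
        assert report.n_samples_removed == 0
        np.testing.assert_allclose(mean_r.to_numpy(), 1.0)

    def test_zero_threshold_removes_none(self):
        rng = np.random.default_rng(5)
        bm = make_beta(rng.uniform(size=(50, 5)))
        out, _, report = interarray_correlation_filter(bm, min_r=0.0)
        assert report.n_samples_removed == 0

    def test_too_few_samples_errors(self):
        bm = make_beta(np.full((5, 2), 0.5))
        with pytest.raises(ValueError, match="3 samples"):
            interarray_correlation_filter(bm)


class TestCascade:
    def test_final_counts_match_generator_bookkeeping(self, tiny_sim):
        cfg, bm, sheet, ann, truth = tiny_sim
        processed, reports = run_preprocess(bm, ann, sheet, PreprocessConfig(bmiq=False))
        expected_sites = (
            bm.n_sites
            - cfg.n_offepic_cpgs
            - (cfg.n_failed_detection_sites + cfg.n_low_bead_sites)
            - cfg.n_crosshyb_cpgs
            - cfg.n_nonvariable_cpgs
        )
        expected_samples = bm.n_samples - cfg.n_noise_samples - cfg.n_sex_mislabels
        assert processed.n_sites == expected_sites
        assert processed.n_samples == expected_samples
        assert not processed.beta.isna().any().any()

    def test_all_steps_disabled_is_identity(self, tiny_sim):
        _, bm, sheet, ann, _ = tiny_sim
        cfg = PreprocessConfig(
            platform_overlap=False, quality_filter=False, impute=False,
            flag_filter=False, sample_qc=False, bmiq=False,
        )
        processed, reports = run_preprocess(bm, ann, sheet, cfg)
        assert processed.beta.equals(bm.beta)
        assert reports == []

    def test_step_order_matches_cascade(self, tiny_sim):
        _, bm, sheet, ann, _ = tiny_sim
        _, reports = run_preprocess(bm, ann, sheet, PreprocessConfig(bmiq=False))
        assert [r.step for r in reports] == [
            "platform_overlap",
            "quality_filter",
            "flagged_sites",
            "interarray_correlation",
            "sex_concordance",
        ]

    def test_filtering_idempotent(self, tiny_sim):
        _, bm, sheet, ann, _ = tiny_sim
        cfg = PreprocessConfig(bmiq=False)
        once, _ = run_preprocess(bm, ann, sheet, cfg)
        twice, reports = run_preprocess(once, ann, sheet, cfg)
        assert twice.beta.shape == once.beta.shape
        assert all(r.n_sites_removed == 0 and r.n_samples_removed == 0 for r in reports)

    def test_defect_free_matrix_unchanged(self):
        cfg = SimulationConfig(
            seed=13, n_snp_probes=20, n_mqtl_cpgs=30, n_background_cpgs=900,
            n_nonvariable_cpgs=0, n_crosshyb_cpgs=0, n_offepic_cpgs=0,
            n_sexchr_cpgs=20, n_cohorts=2, cohort_sizes=(15, 15),
            n_failed_detection_sites=0, n_low_bead_sites=0, n_sporadic_failures=0,
            n_noise_samples=0, n_sex_mislabels=0,
        )
        bm, sheet, ann, _ = simulate_cohorts(cfg)
        processed, reports = run_preprocess(bm, ann, sheet, PreprocessConfig(bmiq=False))
        assert processed.n_sites == bm.n_sites
        assert processed.n_samples == bm.n_samples

    def test_every_removed_id_in_exactly_one_step(self, tiny_sim):
        _, bm, sheet, ann, _ = tiny_sim
        _, reports = run_preprocess(bm, ann, sheet, PreprocessConfig(bmiq=False))
        all_sites = [s for r in reports for s in r.sites_removed]
        all_samples = [s for r in reports for s in r.samples_removed]
        assert len(all_sites) == len(set(all_sites))
        assert len(all_samples) == len(set(all_samples))
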