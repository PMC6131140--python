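"""Generator ground truth, determinism and configuration validation."""

import numpy as np
import pandas as pd
import pytest

from meningiomics.synthetic_cohort import (
    CohortConfig,
    ConfigurationError,
    DriverSpec,
    simulate_catalogues,
    simulate_cohort,
    simulate_expression,
    simulate_methylation,
    simulate_segments,
    simulate_survival,
)


class TestDeterminism:
    def test_expression_identical_under_same_seed(self):
        a, _ = simulate_expression(CohortConfig(seed=77))
        b, _ = simulate_expression(CohortConfig(seed=77))
        assert np.array_equal(a.values, b.values)
        assert a.gene_ids == b.gene_ids

    def test_all_layers_identical_under_same_seed(self):
        c1 = simulate_cohort(CohortConfig(seed=42))
        c2 = simulate_cohort(CohortConfig(seed=42))
        assert np.array_equal(c1.counts.values, c2.counts.values)
        pd.testing.assert_frame_equal(c1.survival, c2.survival)
        pd.testing.assert_frame_equal(c1.beta.beta, c2.beta.beta)
        pd.testing.assert_frame_equal(c1.catalogue.counts, c2.catalogue.counts)
        for p1, p2 in zip(c1.segments, c2.segments):
            pd.testing.assert_frame_equal(p1.segments, p2.segments)

    def test_different_seed_changes_counts(self):
        a, _ = simulate_expression(CohortConfig(seed=1))
        b, _ = simulate_expression(CohortConfig(seed=2))
        assert not np.array_equal(a.values, b.values)


class TestExpressionGroundTruth:
    def test_planted_markers_have_largest_group_mean_ratios(self):
        cfg = CohortConfig(seed=8, dispersion=0.05)
        counts, truth = simulate_expression(cfg)
        c1 = [s for s in counts.sample_ids if truth.labels[s] == "C1"]
        c2 = [s for s in counts.sample_ids if truth.labels[s] == "C2"]
        frame = counts.to_frame()
        ratio = np.abs(
            np.log2((frame[c1].mean(axis=1) + 0.5) / (frame[c2].mean(axis=1) + 0.5))
        )
        top6 = set(ratio.nlargest(6).index)
        assert top6 == set(truth.marker_ids)

    def test_null_config_no_systematic_group_difference(self):
        # after depth normalisation, group-mean log differences centre on 0
        shifts = []
        for seed in range(5):
            cfg = CohortConfig(seed=seed, marker_lfc=0.0, n_markers=0)
            counts, truth = simulate_expression(cfg)
            counts = counts.with_size_factors()
            norm = counts.values / counts.size_factors[None, :]
            frame = pd.DataFrame(
                np.log2(norm + 1), index=counts.gene_ids, columns=counts.sample_ids
            )
            c1 = [s for s in counts.sample_ids if truth.labels[s] == "C1"]
            c2 = [s for s in counts.sample_ids if truth.labels[s] == "C2"]
            d = frame[c1].mean(axis=1) - frame[c2].mean(axis=1)
            shifts.append(d.mean())
        assert abs(np.mean(shifts)) < 0.02

    def test_control_genes_present_and_disjoint_from_markers(self):
        counts, truth = simulate_expression(CohortConfig(seed=3))
        assert set(truth.control_gene_ids) <= set(counts.gene_ids)
        assert not set(truth.control_gene_ids) & set(truth.marker_ids)

    def test_ground_truth_ids_exist_everywhere(self):
        cohort = simulate_cohort(CohortConfig(seed=10))
        assert set(cohort.truth.marker_ids) <= set(cohort.counts.gene_ids)
        assert set(cohort.truth.diff_probe_ids) <= set(cohort.beta.probe_ids)
        samples = set(cohort.counts.sample_ids)
        assert set(cohort.truth.labels) == samples
        for s, gene, _ in cohort.truth.driver_events:
            assert s in samples
            assert gene in set(cohort.config.gene_table["gene"])


class TestSurvivalGenerator:
    def test_rates_reflect_hazard_ratio(self):
        times = {"C1": [], "C2": []}
        for seed in range(30):
            cfg = CohortConfig(seed=seed, censor_time=1e9)
            rec = simulate_survival(cfg)
            for grp in times:
                times[grp].extend(rec[rec.group == grp]["time"])
        ratio = np.mean(times["C2"]) / np.mean(times["C1"])
        assert 12 < ratio < 23  # true HR 17

    def test_invalid_rates_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_survival(CohortConfig(surv_baseline_rate=0.0))
        with pytest.raises(ConfigurationError):
            simulate_survival(CohortConfig(surv_hr=-1.0))

    def test_labels_must_cover_samples(self):
        cfg = CohortConfig(seed=0)
        with pytest.raises(ConfigurationError, match="missing"):
            simulate_survival(cfg, labels={"AM01": "C1"})


class TestMethylationGenerator:
    def test_planted_probes_have_largest_group_differences(self):
        cfg = CohortConfig(seed=5)
        bm, _, truth = simulate_methylation(cfg)
        c1 = [s for s in bm.sample_ids if truth.labels[s] == "C1"]
        c2 = [s for s in bm.sample_ids if truth.labels[s] == "C2"]
        diff = (bm.beta[c1].mean(axis=1) - bm.beta[c2].mean(axis=1)).abs()
        top = set(diff.nlargest(len(truth.diff_probe_ids)).index)
        assert top == set(truth.diff_probe_ids)

    def test_beta_within_unit_interval(self):
        bm, _, _ = simulate_methylation(CohortConfig(seed=6))
        b = bm.beta.to_numpy()
        assert b.min() >= 0 and b.max() <= 1

    def test_planted_delta_close_to_target(self):
        cfg = CohortConfig(seed=7)
        bm, _, truth = simulate_methylation(cfg)
        c1 = [s for s in bm.sample_ids if truth.labels[s] == "C1"]
        c2 = [s for s in bm.sample_ids if truth.labels[s] == "C2"]
        diff = (
            bm.beta.loc[truth.diff_probe_ids, c1].mean(axis=1)
            - bm.beta.loc[truth.diff_probe_ids, c2].mean(axis=1)
        ).abs()
        # logistic noise attenuates the planted difference slightly
        assert diff.mean() == pytest.approx(cfg.delta_beta_true, abs=0.06)

    def test_infeasible_delta_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(delta_beta_true=0.95).validate()


class TestSegmentGenerator:
    def test_planted_homdel_called_in_exactly_those_samples(self):
        from meningiomics.copy_number import call_cnv_drivers

        cfg = CohortConfig(
            seed=12, drivers=[DriverSpec("CDKN2A", "homozygous_deletion", n_samples=3)]
        )
        profiles, truth = simulate_segments(cfg)
        expected = {s for s, g, t in truth.driver_events}
        called = set()
        for prof in profiles:
            for c in call_cnv_drivers(prof, cfg.gene_table):
                if c.gene == "CDKN2A" and c.type == "homozygous_deletion":
                    called.add(c.sample)
        assert called == expected

    def test_segments_tile_without_overlap(self):
        profiles, _ = simulate_segments(CohortConfig(seed=13))
        for prof in profiles:
            for chrom, grp in prof.segments.groupby("chrom"):
                g = grp.sort_values("start")
                assert (g["start"].iloc[0]) == 1
                assert (g["start"].to_numpy()[1:] == g["end"].to_numpy()[:-1] + 1).all()

    def test_explicit_segment_spec_passthrough_and_validation(self):
        spec = {"AM01": ([("1", 1, 100, 2)], 2.0)}
        cfg = CohortConfig(seed=0, segments_spec=spec)
        profiles, _ = simulate_segments(cfg)
        assert profiles[0].sample == "AM01"
        bad = {"AM01": ([("1", 100, 50, 2)], 2.0)}
        with pytest.raises(ValueError, match="end < start"):
            simulate_segments(CohortConfig(seed=0, segments_spec=bad))


class TestCatalogueGenerator:
    def test_single_signature_profile_matches_by_cosine(self):
        from meningiomics.mutational_signatures import cosine_similarity
        from meningiomics.synthetic_cohort import make_default_signatures

        cfg = CohortConfig(
            seed=14,
            n_c1=5, n_c2=5,
            signature_profiles=make_default_signatures(1),
            exposure_matrix_true=np.full((10, 1), 1000.0),
        )
        cat, _ = simulate_catalogues(cfg)
        prof = cat.counts.to_numpy().sum(axis=0).astype(float)
        prof /= prof.sum()
        assert cosine_similarity(prof, make_default_signatures(1)[0]) >= 0.97

    def test_negative_exposures_rejected(self):
        cfg = CohortConfig(exposure_matrix_true=np.array([[-1.0, 2.0]] * 25))
        with pytest.raises(ConfigurationError):
            simulate_catalogues(cfg)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_c1": 1, "n_c2": 1},
            {"n_markers": 5000},
            {"n_diff_probes": 5000},
            {"delta_beta_true": 1.5},
            {"censor_time": -1.0},
            {"dispersion": -0.1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            CohortConfig(**kwargs).validate()

    def test_bad_signature_profiles_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(signature_profiles=np.ones((2, 96))).validate()
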