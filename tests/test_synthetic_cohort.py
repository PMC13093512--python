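import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainsim.synthetic_cohort import (
    BIOMARKERS,
    COGNITIVE_TESTS,
    ConfigurationError,
    SimConfig,
    block_correlation,
    cytoarch_block_sizes,
    generate_biomarkers,
    generate_cohort,
    generate_conversion_labels,
    generate_longitudinal_cognition,
    generate_reference_cohort,
    generate_target_subjects,
    nearest_psd_correlation,
    perturbed_covariance,
)


class TestConfigValidation:
    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ConfigurationError, match="positive semidefinite"):
            SimConfig(n_regions=3, base_covariance=bad, perturbed_edges=[(0, 1)])

    def test_perturbation_strength_bounds(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_regions=12, perturbation_strength=1.0)

    def test_too_few_visits_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_regions=12, n_visits=1)

    def test_invalid_edge_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_regions=12, perturbed_edges=[(0, 12)])

    def test_json_round_trip(self, small_cfg):
        clone = SimConfig.from_json(small_cfg.to_json())
        assert clone.n_regions == small_cfg.n_regions
        np.testing.assert_array_equal(clone.base_covariance, small_cfg.base_covariance)
        assert clone.perturbed_edges == small_cfg.perturbed_edges


class TestCovarianceMachinery:
    def test_block_sizes_partition_regions(self):
        for n in (10, 20, 34, 68):
            sizes = cytoarch_block_sizes(n)
            assert sizes.sum() == n and (sizes >= 1).all() and len(sizes) == 7

    def test_block_correlation_is_psd_unit_diag(self):
        mat = block_correlation(20)
        assert np.allclose(np.diag(mat), 1.0)
        assert np.linalg.eigvalsh(mat).min() > 0

    def test_psd_repair_projects_and_rescales(self):
        mat = block_correlation(10)
        mat[0, 1] = mat[1, 0] = -0.95  # break PSD
        fixed = nearest_psd_correlation(mat)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        assert np.allclose(np.diag(fixed), 1.0)

    def test_zero_strength_leaves_base_untouched(self, small_cfg):
        cfg = SimConfig(n_regions=12, perturbation_strength=0.0)
        out = perturbed_covariance(cfg, exposure=1.0, multiplier=1.0)
        np.testing.assert_array_equal(out, cfg.base_covariance)

    def test_planted_shift_matches_monte_carlo(self):
        """Sampling from the perturbed covariance moves the planted edge's
        sample correlation by ~ -strength (large-sample check)."""
        cfg = SimConfig(n_regions=10, perturbed_edges=[(0, 1)],
                        perturbation_strength=0.3, seed=3)
        cov = perturbed_covariance(cfg, exposure=1.0, multiplier=1.0)
        rng = np.random.default_rng(42)
        draws = rng.multivariate_normal(np.zeros(10), cov, size=2000)
        r = np.corrcoef(draws, rowvar=False)[0, 1]
        assert abs(r - (cfg.base_covariance[0, 1] - 0.3)) < 0.05


class TestReferenceCohort:
    def test_shapes_match_adni_like_defaults(self):
        cfg = SimConfig(seed=1)  # 114 reference subjects, 68 regions
        ref = generate_reference_cohort(cfg)
        assert ref["subject_id"].nunique() == 114
        assert len(cfg.thickness_columns) == 68
        assert set(ref["group"]) == {"stable_negative"}

    def test_determinism_bit_identical(self, small_cfg):
        a = generate_cohort(small_cfg)
        b = generate_cohort(small_cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_covariate_betas_center_on_mean(self):
        cfg = SimConfig(n_reference=300, n_regions=10, seed=5,
                        covariate_betas={"age": 0.0, "sex": 0.0, "education": 0.0})
        ref = generate_reference_cohort(cfg)
        base = ref[ref.visit_time == 0]
        vals = base[cfg.thickness_columns].to_numpy()
        se = vals.std(axis=0) / np.sqrt(len(base))
        assert (np.abs(vals.mean(axis=0) - cfg.thickness_mean) < 4 * se).all()

    def test_visit_times_strictly_increasing(self, small_cohort):
        for _, grp in small_cohort.groupby("subject_id"):
            t = grp["visit_time"].to_numpy()
            assert (np.diff(t) > 0).all() and t.min() >= 0


class TestTargetSubjects:
    def test_group_sizes_match_config(self):
        cfg = SimConfig(n_reference=10, n_incident=26, n_elevated=45,
                        n_regions=10, seed=2)
        targets = generate_target_subjects(cfg)
        counts = targets.drop_duplicates("subject_id")["group"].value_counts()
        assert counts["incident_positive"] == 26
        assert counts["elevated_positive"] == 45

    def test_thickness_vector_length(self, small_cohort, small_cfg):
        assert len(small_cfg.thickness_columns) == small_cfg.n_regions
        assert small_cohort[small_cfg.thickness_columns].notna().all().all()


class TestCognition:
    def test_noiseless_scores_linear_in_time(self):
        cfg = SimConfig(n_reference=5, n_incident=5, n_elevated=5, n_regions=10,
                        n_visits=4, residual_sd=0.0, random_intercept_sd=0.0,
                        deviation_mode="product", seed=9)
        cohort = generate_longitudinal_cognition(generate_target_subjects(cfg), cfg)
        for test in COGNITIVE_TESTS:
            for _, grp in cohort.groupby("subject_id"):
                y = grp.sort_values("visit_time")[test].to_numpy()
                assert np.allclose(np.diff(y, n=2), 0.0, atol=1e-9)

    def test_null_interaction_pvalues_uniform(self):
        """With no planted slope effect, the interaction p-value from the
        screening model is uniform across replicates (KS test)."""
        from brainsim.lme_screening import fit_interaction_lme

        pvals = []
        for seed in range(300):
            cfg = SimConfig(n_reference=5, n_incident=20, n_elevated=20,
                            n_regions=10, n_visits=3, interaction_beta=0.0,
                            deviation_mode="product", seed=seed)
            cohort = generate_longitudinal_cognition(
                generate_target_subjects(cfg), cfg
            )
            cohort["z"] = (cohort["lmdrt"] - 14.0) / 4.0
            res = fit_interaction_lme(cohort, "z", "deviation")
            pvals.append(res.p_interaction)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_network_deviation_zero_for_reference(self, small_cohort):
        ref = small_cohort[small_cohort.group == "stable_negative"]
        assert (ref["deviation"] == 0).all()


class TestBiomarkers:
    def test_strictly_positive(self, small_cohort):
        base = small_cohort[small_cohort.visit_time == 0]
        assert (base[list(BIOMARKERS)] > 0).all().all()

    def test_baseline_only(self, small_cohort):
        later = small_cohort[small_cohort.visit_time > 0]
        assert later[list(BIOMARKERS)].isna().all().all()

    def test_zero_shift_equal_medians(self):
        cfg = SimConfig(n_reference=400, n_incident=400, n_elevated=0,
                        n_regions=10, biomarker_group_shift=0.0,
                        deviation_mode="latent", perturbation_strength=0.0, seed=11)
        cohort = pd.concat(
            [generate_reference_cohort(cfg), generate_target_subjects(cfg)],
            ignore_index=True,
        )
        out = generate_biomarkers(cohort, cfg)
        base = out[out.visit_time == 0]
        med = base.groupby(base.group == "stable_negative")["csf_ptau181"].median()
        assert abs(np.log(med[True] / med[False])) < 0.1

    def test_log_shift_moves_median_by_exp_factor(self):
        cfg = SimConfig(n_reference=1000, n_incident=1000, n_elevated=0,
                        n_regions=10, biomarker_group_shift=0.5,
                        deviation_mode="latent", perturbation_strength=0.0, seed=12)
        cohort = pd.concat(
            [generate_reference_cohort(cfg), generate_target_subjects(cfg)],
            ignore_index=True,
        )
        out = generate_biomarkers(cohort, cfg)
        base = out[out.visit_time == 0]
        pos = base[base.group != "stable_negative"]["csf_ttau"].median()
        neg = base[base.group == "stable_negative"]["csf_ttau"].median()
        assert abs(pos / neg - np.exp(0.5)) < 0.05 * np.exp(0.5)


class TestConversion:
    @staticmethod
    def _toy_cohort(n, rng):
        return pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "visit_time": 0.0,
                "group": "incident_positive",
                "deviation": rng.normal(0, 1, n),
            }
        )

    def test_zero_betas_give_half_rate(self):
        cfg = SimConfig(n_regions=10, conversion_betas=(0.0, 0.0), seed=21)
        cohort = self._toy_cohort(10000, np.random.default_rng(0))
        out = generate_conversion_labels(cohort, cfg)
        assert abs(out["converted"].mean() - 0.5) < 0.02

    def test_positive_beta_converters_have_higher_deviation(self):
        cfg = SimConfig(n_regions=10, conversion_betas=(0.0, 3.0), seed=22)
        cohort = self._toy_cohort(2000, np.random.default_rng(1))
        out = generate_conversion_labels(cohort, cfg)
        conv = out[out.converted == 1]["deviation"]
        non = out[out.converted == 0]["deviation"]
        assert stats.ttest_ind(conv, non, alternative="greater").pvalue < 1e-6

    def test_labels_deterministic(self):
        cfg = SimConfig(n_regions=10, seed=23)
        cohort = self._toy_cohort(500, np.random.default_rng(2))
        a = generate_conversion_labels(cohort, cfg)["converted"]
        b = generate_conversion_labels(cohort, cfg)["converted"]
        assert (a == b).all()
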