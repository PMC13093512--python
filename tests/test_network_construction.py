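import numpy as np
import pandas as pd
import pytest

from brainsim.network_construction import (
    build_individual_network,
    build_reference_network,
    edge_names,
    icc_consistency,
    residualize,
    stability_curve,
)
from brainsim.synthetic_cohort import SimConfig, generate_cohort


def brute_force_residuals(values, covariates):
    """Normal-equations least squares, independent of the library path."""
    n = values.shape[0]
    X = np.column_stack([np.ones(n), covariates])
    beta = np.linalg.solve(X.T @ X, X.T @ values)
    return values - X @ beta


class TestResidualize:
    def test_intercept_only_is_centering(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(20, 4))
        out = residualize(vals, None)
        np.testing.assert_allclose(out, vals - vals.mean(axis=0), atol=1e-12)

    def test_perfect_linear_fit_gives_zero_residuals(self):
        rng = np.random.default_rng(1)
        covs = rng.normal(size=(25, 3))
        vals = covs @ rng.normal(size=(3, 5)) + 2.0
        out = residualize(vals, covs)
        assert np.abs(out).max() < 1e-10

    def test_matches_normal_equations_and_orthogonality(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(30, 6))
        covs = rng.normal(size=(30, 5))
        out = residualize(vals, covs)
        np.testing.assert_allclose(out, brute_force_residuals(vals, covs), atol=1e-10)
        centered = covs - covs.mean(axis=0)
        corr = out.T @ centered / len(out)
        assert np.abs(corr).max() < 1e-10

    def test_rank_deficiency_names_collinear_columns(self):
        rng = np.random.default_rng(3)
        covs = rng.normal(size=(20, 2))
        covs = np.column_stack([covs, covs[:, 0]])
        with pytest.raises(ValueError, match="collinear"):
            residualize(rng.normal(size=(20, 3)), covs)

    def test_zero_variance_covariate_dropped(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(15, 2))
        covs = np.column_stack([np.full(15, 3.0), rng.normal(size=15)])
        out = residualize(vals, covs)
        assert out.shape == vals.shape


class TestPartialCorrelationOracle:
    def test_matches_single_covariate_recursion(self):
        """residualize-then-Pearson equals the textbook partial correlation
        r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            data = rng.normal(size=(rng.integers(10, 40), 3))
            data[:, 1] += 0.5 * data[:, 0]
            data[:, 2] += 0.3 * data[:, 0]
            resid = residualize(data[:, :2], data[:, 2:3])
            ours = np.corrcoef(resid, rowvar=False)[0, 1]
            r = np.corrcoef(data, rowvar=False)
            rxy, rxz, ryz = r[0, 1], r[0, 2], r[1, 2]
            textbook = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
            assert abs(ours - textbook) < 1e-10


def _cohort_frame(values, covs=None, prefix="thick_r"):
    n, p = values.shape
    frame = pd.DataFrame(values, columns=[f"{prefix}{i}" for i in range(p)])
    frame["subject_id"] = [f"S{i}" for i in range(n)]
    frame["visit_time"] = 0.0
    if covs is not None:
        frame[["age", "sex", "education"]] = covs
    return frame


class TestReferenceNetwork:
    def test_reduces_to_pearson_without_covariates(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(40, 5))
        net = build_reference_network(_cohort_frame(vals), covariates=())
        np.testing.assert_allclose(
            net.matrix, np.corrcoef(vals, rowvar=False), atol=1e-10
        )

    def test_duplicate_region_rejected(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(30, 3))
        vals = np.column_stack([vals, vals[:, 0]])
        with pytest.raises(ValueError, match="duplicate|collinear|\\|r\\|=1"):
            build_reference_network(_cohort_frame(vals), covariates=())

    def test_recovers_known_partial_correlation(self):
        """Two regions with partial correlation 0.6 given covariates."""
        rng = np.random.default_rng(8)
        n = 5000
        covs = rng.normal(size=(n, 3))
        latent = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=n)
        vals = latent + covs @ np.array([[0.5, -0.2], [0.1, 0.4], [0.3, 0.3]])
        frame = _cohort_frame(vals, covs)
        net = build_reference_network(frame)
        assert abs(net.matrix[0, 1] - 0.6) < 0.03

    def test_symmetry_exact(self, small_cohort):
        ref = small_cohort[small_cohort.group == "stable_negative"]
        net = build_reference_network(ref)
        assert np.array_equal(net.matrix, net.matrix.T)
        assert np.allclose(np.diag(net.matrix), 1.0)


@pytest.fixture(scope="module")
def nets(small_cohort):
    ref = small_cohort[small_cohort.group == "stable_negative"]
    ref_net = build_reference_network(ref)
    row = small_cohort[small_cohort.group == "incident_positive"].iloc[0]
    return ref, ref_net, build_individual_network(row, ref, ref_net)


class TestIndividualNetwork:

    def test_z_standardization_exact(self, nets):
        _, _, isn = nets
        iu = np.triu_indices(isn.z_matrix.shape[0], k=1)
        assert abs(isn.z_matrix[iu].mean()) < 1e-10
        assert abs(isn.z_matrix[iu].std() - 1.0) < 1e-10
        assert (np.diag(isn.z_matrix) == 0).all()

    def test_matrices_exactly_symmetric(self, nets):
        _, _, isn = nets
        assert np.array_equal(isn.z_matrix, isn.z_matrix.T)
        assert np.array_equal(isn.raw_difference, isn.raw_difference.T)

    def test_reference_subject_rejected(self, small_cohort):
        ref = small_cohort[small_cohort.group == "stable_negative"]
        ref_net = build_reference_network(ref)
        with pytest.raises(ValueError, match="reference group"):
            build_individual_network(ref.iloc[0], ref, ref_net)

    def test_missing_covariate_rejected(self, small_cohort):
        ref = small_cohort[small_cohort.group == "stable_negative"]
        ref_net = build_reference_network(ref)
        row = small_cohort[small_cohort.group == "incident_positive"].iloc[0].copy()
        row["age"] = np.nan
        with pytest.raises(ValueError, match="covariate"):
            build_individual_network(row, ref, ref_net)

    def test_duplicated_subject_perturbs_little_at_reference_scale(self):
        """A subject identical to a reference member changes the network by
        O(1/n); at n = 114 the largest edge change stays below 0.05."""
        cfg = SimConfig(n_reference=114, n_incident=1, n_elevated=0,
                        n_regions=10, seed=31)
        cohort = generate_cohort(cfg)
        ref = cohort[cohort.group == "stable_negative"]
        ref_net = build_reference_network(ref)
        clone = ref[ref.visit_time == 0].iloc[0].copy()
        clone["subject_id"] = "CLONE"
        isn = build_individual_network(clone, ref, ref_net)
        assert np.abs(isn.raw_difference).max() < 0.05

    def test_perturbation_locality_shrinks_with_reference_size(self):
        """Median max |raw difference| of an in-distribution subject strictly
        decreases as the reference grows."""
        medians = []
        for n_ref in (50, 200, 800):
            cfg = SimConfig(n_reference=n_ref, n_incident=8, n_elevated=0,
                            n_regions=8, perturbation_strength=0.0, seed=32,
                            deviation_mode="latent")
            cohort = generate_cohort(cfg)
            ref = cohort[cohort.group == "stable_negative"]
            ref_net = build_reference_network(ref)
            targets = cohort[(cohort.group == "incident_positive")
                             & (cohort.visit_time == 0)]
            vals = [
                np.abs(build_individual_network(r, ref, ref_net).raw_difference).max()
                for _, r in targets.iterrows()
            ]
            medians.append(np.median(vals))
        assert medians[0] > medians[1] > medians[2]

    def test_planted_edges_rank_high_in_group_mean_z(self):
        """Averaging the signed z matrices over many perturbed subjects
        cancels the single-subject realization noise and leaves the planted
        shift: the planted edge set ranks above the 90th percentile of the
        |group-mean z| distribution."""
        cfg = SimConfig(n_reference=100, n_incident=200, n_elevated=0,
                        n_regions=16, n_visits=2,
                        perturbation_strength=0.4, seed=33)
        cohort = generate_cohort(cfg)
        ref = cohort[cohort.group == "stable_negative"]
        ref_net = build_reference_network(ref)
        targets = cohort[(cohort.group == "incident_positive")
                         & (cohort.visit_time == 0)]
        zsum = np.zeros((16, 16))
        for _, row in targets.iterrows():
            zsum += build_individual_network(row, ref, ref_net).z_matrix
        zmean = zsum / len(targets)
        iu = np.triu_indices(16, k=1)
        all_edges = np.abs(zmean[iu])
        pct = [float(np.mean(all_edges <= abs(zmean[j, k])))
               for j, k in cfg.perturbed_edges]
        assert np.mean(pct) >= 0.9
        assert sum(p >= 0.9 for p in pct) >= 4


class TestICC:
    def test_identity_is_one(self):
        a = np.random.default_rng(0).normal(size=50)
        assert icc_consistency(a, a) == pytest.approx(1.0)

    def test_constant_shift_invariance(self):
        a = np.random.default_rng(1).normal(size=50)
        assert icc_consistency(a, a + 3.7) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(2)
        icc = icc_consistency(rng.normal(size=10000), rng.normal(size=10000))
        assert abs(icc) < 0.03

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            icc_consistency(np.ones(10), np.ones(10))

    def test_matches_pingouin_two_way_mixed(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        a = rng.normal(size=40)
        b = 0.8 * a + rng.normal(0, 0.5, 40)
        table = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(40), 2),
                "raters": np.tile(["A", "B"], 40),
                "score": np.column_stack([a, b]).ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            table, targets="targets", raters="raters", ratings="score"
        )
        icc3 = ref.loc[ref["Type"].isin(["ICC3", "ICC(C,1)"]), "ICC"].iloc[0]
        assert icc_consistency(a, b) == pytest.approx(icc3, abs=1e-10)


class TestStabilityCurve:
    def test_full_sample_point_is_one_and_defaults(self, small_cohort):
        import inspect
        from brainsim.network_construction import stability_curve as sc

        sig = inspect.signature(sc)
        assert sig.parameters["n_reps"].default == 1000
        assert sig.parameters["threshold"].default == 0.75

        ref = small_cohort[small_cohort.group == "stable_negative"]
        curve = stability_curve(ref, sizes=[10, 30], n_reps=5, seed=0)
        assert curve.mean_icc[-1] == pytest.approx(1.0)

    def test_small_sizes_skipped(self, small_cohort):
        ref = small_cohort[small_cohort.group == "stable_negative"]
        curve = stability_curve(ref, sizes=[2, 10], n_reps=3, seed=0)
        assert list(curve.sample_sizes) == [10]

    def test_oversized_grid_rejected(self, small_cohort):
        ref = small_cohort[small_cohort.group == "stable_negative"]
        with pytest.raises(ValueError, match="exceeds"):
            stability_curve(ref, sizes=[10, 500], n_reps=2, seed=0)


def test_edge_names_cover_upper_triangle():
    names = edge_names(["a", "b", "c"])
    assert names == ["a|b", "a|c", "b|c"]
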