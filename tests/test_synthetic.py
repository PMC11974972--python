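"""Ground-truth behaviour of the synthetic cohort generators."""

import numpy as np
import pytest
from scipy import stats

from msnbiotyper.msn import build_msn_equal_voxels
from msnbiotyper.synthetic import (
    BiotypePlan,
    CohortSpec,
    generate_annotation_maps,
    generate_centroids,
    generate_control_hubness,
    generate_covariates,
    generate_fusion_stacks,
    generate_regional_samples,
    plant_biotypes,
    symptom_scores_for_biotypes,
)


class TestCovariates:
    def test_degenerate_counts(self):
        cov = generate_covariates(CohortSpec(0, 10))
        assert len(cov) == 10 and (cov["group"] == "control").all()

    def test_sex_ratio_boundary(self):
        cov = generate_covariates(CohortSpec(5, 5, sex_ratio=1.0))
        assert (cov["sex"] == 1).all()

    def test_sex_ratio_within_binomial_band(self):
        cov = generate_covariates(CohortSpec(1000, 1000, sex_ratio=0.7, seed=9))
        n = len(cov)
        frac = cov["sex"].mean()
        half_width = 2.576 * np.sqrt(0.7 * 0.3 / n)  # binomial 99% interval
        assert abs(frac - 0.7) < half_width

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(10, 10, age_range=(14, 7))
        with pytest.raises(ValueError):
            CohortSpec(10, 10, sex_ratio=1.5)
        with pytest.raises(ValueError):
            CohortSpec(-1, 10)

    def test_reproducible_for_fixed_seed(self):
        a = generate_covariates(CohortSpec(20, 20, seed=3))
        b = generate_covariates(CohortSpec(20, 20, seed=3))
        assert a.equals(b)

    def test_sites_roughly_balanced(self):
        cov = generate_covariates(CohortSpec(30, 30, n_sites=3, seed=1))
        counts = cov["site"].value_counts()
        assert counts.max() - counts.min() <= 1


class TestControlHubness:
    def test_zero_noise_limit_equals_mean_function(self):
        cov = generate_covariates(CohortSpec(0, 50, seed=4))
        prof, truth = generate_control_hubness(cov, R=3, noise_sd=1e-12, seed=5)
        expected = truth.mean_function(
            1, 2, cov["age"].to_numpy(), cov["sex"].to_numpy(), cov["site"].to_numpy()
        )
        np.testing.assert_allclose(prof.values[:, 1, 2], expected, atol=1e-9)

    def test_design_regression_recovers_offsets(self):
        cov = generate_covariates(CohortSpec(0, 1000, n_sites=2, seed=6))
        prof, truth = generate_control_hubness(cov, R=2, noise_sd=0.3, seed=7)
        y = prof.values[:, 0, 0]
        lo, hi = truth.age_range
        a = 2 * (cov["age"].to_numpy() - lo) / (hi - lo) - 1
        X = np.column_stack([
            np.ones_like(a), a, a**2, a**3,
            cov["sex"].to_numpy(), (cov["site"] == 1).to_numpy().astype(float),
        ])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(y) - X.shape[1])
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        true_beta = np.r_[
            truth.age_coefficients[0, 0, 0] + truth.site_offsets[0, 0, 0],
            truth.age_coefficients[0, 0, 1:4],
            truth.sex_offsets[0, 0],
            truth.site_offsets[1, 0, 0] - truth.site_offsets[0, 0, 0],
        ]
        assert np.all(np.abs(beta - true_beta) < 3 * se)

    def test_residuals_gaussian_after_design_regression(self):
        cov = generate_covariates(CohortSpec(0, 1000, n_sites=1, seed=8))
        prof, truth = generate_control_hubness(cov, R=2, noise_sd=0.25, seed=9)
        y = prof.values[:, 0, 0]
        mean = truth.mean_function(0, 0, cov["age"], cov["sex"], cov["site"])
        assert stats.normaltest(y - mean).pvalue > 0.01

    def test_bad_noise_rejected(self):
        cov = generate_covariates(CohortSpec(0, 5))
        with pytest.raises(ValueError):
            generate_control_hubness(cov, R=3, noise_sd=0.0)


class TestPlantBiotypes:
    @pytest.fixture
    def cohort(self):
        cov = generate_covariates(CohortSpec(400, 400, seed=10))
        prof, truth = generate_control_hubness(cov, R=6, noise_sd=0.3, seed=11)
        return cov, prof, truth

    def test_zero_effect_is_identity(self, cohort):
        cov, prof, _ = cohort
        plan = BiotypePlan(2, [[0], [1]], np.zeros((2, 3)))
        out, _ = plant_biotypes(prof, cov, plan, seed=12)
        np.testing.assert_array_equal(out.values, prof.values)

    def test_three_sd_shift_recovered_by_sample_means(self, cohort):
        cov, prof, _ = cohort
        plan = BiotypePlan(1, [[5]], np.array([[3.0, 0.0, 0.0]]))
        out, truth = plant_biotypes(prof, cov, plan, seed=13)
        case = (cov["group"] == "case").to_numpy()
        sd = prof.values[~case, 5, 0].std(ddof=1)
        diff = out.values[case, 5, 0].mean() - out.values[~case, 5, 0].mean()
        assert diff / sd == pytest.approx(3.0, abs=0.2)
        # other regions and metrics untouched
        np.testing.assert_array_equal(out.values[:, :5], prof.values[:, :5])
        np.testing.assert_array_equal(out.values[~case], prof.values[~case])

    def test_degenerate_simplex_gives_single_label(self, cohort):
        cov, prof, _ = cohort
        plan = BiotypePlan(3, [[0], [1], [2]], np.ones((3, 3)),
                           assignment_probs=[1.0, 0.0, 0.0])
        _, truth = plant_biotypes(prof, cov, plan, seed=14)
        assert np.all(truth.biotype_labels == 1)

    def test_case_free_cohort_rejected(self):
        cov = generate_covariates(CohortSpec(0, 20, seed=15))
        prof, _ = generate_control_hubness(cov, R=3, seed=16)
        plan = BiotypePlan(1, [[0]], np.ones((1, 3)))
        with pytest.raises(ValueError):
            plant_biotypes(prof, cov, plan)

    def test_symptom_scores_follow_biotype_means(self, cohort):
        cov, prof, _ = cohort
        plan = BiotypePlan(2, [[0], [1]], np.ones((2, 3)),
                           symptom_means=np.array([[0.2, 0.8], [0.8, 0.2]]))
        _, truth = plant_biotypes(prof, cov, plan, seed=17)
        cov2 = symptom_scores_for_biotypes(cov, truth.biotype_labels, plan, seed=18)
        cases = cov2[cov2["group"] == "case"]
        b1 = cases["inattention"].to_numpy()[truth.biotype_labels == 1]
        b2 = cases["inattention"].to_numpy()[truth.biotype_labels == 2]
        assert b1.mean() == pytest.approx(0.2, abs=0.05)
        assert b2.mean() == pytest.approx(0.8, abs=0.05)
        assert cov2["inattention"].between(0, 1).where(cov2["group"] == "case", True).all()


class TestRegionalSamples:
    def _mean_kls_blocks(self, corr, seed):
        cov = generate_covariates(CohortSpec(0, 50, seed=seed))
        partition = np.repeat([0, 1, 2], 4)
        morphs = generate_regional_samples(
            cov, R=12, n_voxels_per_region=30, module_partition=partition,
            within_block_corr=corr, seed=seed,
        )
        within, between = [], []
        for m in morphs:
            W = build_msn_equal_voxels(m.subject_id, np.vstack(m.values)).W
            for i in range(12):
                for j in range(i + 1, 12):
                    (within if partition[i] == partition[j] else between).append(W[i, j])
        return np.mean(within), np.mean(between), within, between

    def test_block_structure_raises_within_block_similarity(self):
        w, b, *_ = self._mean_kls_blocks(0.9, seed=20)
        assert w > b

    def test_no_block_structure_when_corr_zero(self):
        w, b, within, between = self._mean_kls_blocks(0.0, seed=21)
        p = stats.mannwhitneyu(within, between).pvalue
        assert p > 0.01

    def test_single_voxel_degenerate_input_runs(self):
        cov = generate_covariates(CohortSpec(0, 2, seed=22))
        morphs = generate_regional_samples(cov, R=4, n_voxels_per_region=1, seed=23)
        sim = build_msn_equal_voxels("s", np.vstack(morphs[0].values))
        sim.validate()

    def test_invalid_corr_rejected(self):
        cov = generate_covariates(CohortSpec(0, 2))
        with pytest.raises(ValueError):
            generate_regional_samples(cov, R=4, within_block_corr=1.0)


class TestAnnotationMaps:
    def test_rho_one_is_affine_transform(self, rng):
        cent, _ = generate_centroids(20, seed=30)
        target = rng.normal(size=20)
        maps = generate_annotation_maps(target, 1.0, 3, 10.0, cent, seed=31)
        for row in maps.M:
            assert abs(np.corrcoef(row, target)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_rho_zero_mean_correlation_in_fisher_band(self, rng):
        R = 60
        cent, _ = generate_centroids(R, seed=32)
        target = rng.normal(size=R)
        maps = generate_annotation_maps(target, 0.0, 200, 10.0, cent, seed=33)
        cors = [np.corrcoef(row, target)[0, 1] for row in maps.M]
        band = 1.96 / np.sqrt(R - 3) / np.sqrt(200)  # SE of the mean Fisher z
        assert abs(np.arctanh(cors).mean()) < 3 * band + 0.02

    def test_zero_smoothness_is_spatially_independent(self, rng):
        R = 80
        cent, _ = generate_centroids(R, seed=34)
        maps = generate_annotation_maps(rng.normal(size=R), 0.0, 50, 0.0, cent, seed=35)
        # neighbour correlation across maps should be near zero (flat variogram)
        d = np.linalg.norm(cent[:, None] - cent[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nn = d.argmin(axis=1)
        r = np.corrcoef(maps.M.ravel(), maps.M[:, nn].ravel())[0, 1]
        assert abs(r) < 0.05

    def test_smooth_maps_have_positive_neighbour_correlation(self, rng):
        R = 80
        cent, _ = generate_centroids(R, seed=36)
        maps = generate_annotation_maps(rng.normal(size=R), 0.0, 50, 30.0, cent, seed=37)
        d = np.linalg.norm(cent[:, None] - cent[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nn = d.argmin(axis=1)
        r = np.corrcoef(maps.M.ravel(), maps.M[:, nn].ravel())[0, 1]
        assert r > 0.3

    def test_invalid_rho_rejected(self, rng):
        cent, _ = generate_centroids(5, seed=38)
        with pytest.raises(ValueError):
            generate_annotation_maps(rng.normal(size=5), 1.5, 1, 5.0, cent)


def test_fusion_stacks_carry_planted_component():
    stacks, labels, truth = generate_fusion_stacks(100, 100, R=30, seed=40)
    # the case-control loading shift survives projection onto the planted map
    for k, metric in enumerate(("DC", "NE", "PC")):
        proj = stacks[metric] @ truth.planted_component_map[k]
        assert proj[labels == 1].mean() > proj[labels == 0].mean()


def test_generators_bit_identical_for_same_seed():
    a, _, _ = generate_fusion_stacks(20, 20, R=10, seed=41)
    b, _, _ = generate_fusion_stacks(20, 20, R=10, seed=41)
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])
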