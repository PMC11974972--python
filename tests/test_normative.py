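"""Normative model fitting, calibration, evaluation and transfer."""

import numpy as np
import pytest
from scipy import stats

from msnbiotyper import normative
from msnbiotyper.synthetic import CohortSpec, generate_control_hubness, generate_covariates
from msnbiotyper.normative import (
    BLRFit,
    DesignSpec,
    crossval_control_deviations,
    deviation_z,
    evaluate,
    exclude_outliers,
    fit_blr,
    fit_normative_models,
    predict,
    score_deviations,
    site_predictability_check,
    split_cohort,
    transfer_recalibrate,
    yeo_johnson,
)


class TestYeoJohnson:
    def test_symmetric_input_lambda_near_one(self, rng):
        _, lam = yeo_johnson(rng.normal(2.0, 1.0, 1000))
        assert lam == pytest.approx(1.0, abs=0.15)

    def test_lognormal_skew_reduced(self, rng):
        y = rng.lognormal(0.0, 0.8, 1000)
        t, _ = yeo_johnson(y)
        assert abs(stats.skew(t)) < abs(stats.skew(y))

    def test_constant_input_identity_with_warning(self):
        with pytest.warns(UserWarning):
            t, lam = yeo_johnson(np.full(10, 3.0))
        assert lam == 1.0
        np.testing.assert_array_equal(t, np.full(10, 3.0))


class TestSplitCohort:
    def test_ninety_percent_per_site(self):
        cov = generate_covariates(CohortSpec(0, 10, n_sites=1, seed=1))
        train, test = split_cohort(cov, 0.9, seed=2)
        assert len(train) == 9 and len(test) == 1

    def test_cases_always_in_test(self):
        cov = generate_covariates(CohortSpec(30, 100, n_sites=2, seed=3))
        train, test = split_cohort(cov, 0.9, seed=4)
        cases = set(cov.loc[cov["group"] == "case", "subject_id"])
        assert cases <= set(test)
        assert cases.isdisjoint(train)

    def test_per_site_fraction_within_one_subject(self):
        cov = generate_covariates(CohortSpec(0, 200, n_sites=4, seed=5))
        train, _ = split_cohort(cov, 0.9, seed=6)
        tr = cov[cov["subject_id"].isin(train)]
        for site, grp in cov.groupby("site"):
            n_tr = (tr["site"] == site).sum()
            assert abs(n_tr - 0.9 * len(grp)) <= 1


class TestBlr:
    def test_noiseless_linear_recovery(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        w_true = np.array([1.5, -2.0])
        fit = fit_blr(X @ w_true, X)
        np.testing.assert_allclose(fit.weights, w_true, atol=1e-6)

    def test_shrinkage_limit(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(size=40)
        fit = fit_blr(y, X, prior_precision=1e12)
        assert np.all(np.abs(fit.weights) < 1e-6)

    def test_predictive_variance_at_least_noise(self, rng):
        X = rng.normal(size=(100, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=100)
        fit = fit_blr(y, X)
        _, var = predict(fit, rng.normal(size=(20, 4)))
        assert np.all(var >= 1.0 / fit.noise_precision - 1e-12)

    def test_hand_computed_posterior_predictive(self):
        # 3 points, 1 feature, fixed precisions: closed-form conjugate solve
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([1.0, 2.0, 2.5])
        lam = 2.0
        fit = fit_blr(y, X, prior_precision=lam)
        alpha = fit.noise_precision
        A = alpha * X.T @ X + lam * np.eye(1)
        w_hand = (alpha * np.linalg.inv(A) @ X.T @ y)[0]
        assert fit.weights[0] == pytest.approx(w_hand, abs=1e-9)
        x_new = np.array([[2.5]])
        mean, var = predict(fit, x_new)
        assert mean[0] == pytest.approx(2.5 * w_hand, abs=1e-9)
        assert var[0] == pytest.approx(1 / alpha + 2.5**2 * np.linalg.inv(A)[0, 0], abs=1e-9)

    def test_coverage_of_predictive_interval(self, rng):
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([0.5, 1.0]) + rng.normal(0, 0.7, n)
        fit = fit_blr(y[: n // 2], X[: n // 2])
        mean, var = predict(fit, X[n // 2 :])
        covered = np.abs(y[n // 2 :] - mean) <= 1.96 * np.sqrt(var)
        assert covered.mean() == pytest.approx(0.95, abs=0.02)

    def test_design_mismatch_rejected(self, rng):
        fit = fit_blr(rng.normal(size=20), rng.normal(size=(20, 3)))
        with pytest.raises(ValueError):
            predict(fit, rng.normal(size=(5, 4)))


class TestDeviationZ:
    def test_affine_definition(self, rng):
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        y = X @ np.array([1.0, 0.5]) + rng.normal(size=100)
        fit = fit_blr(y, X)
        x0 = np.array([[1.0, 0.3]])
        mean, var = predict(fit, x0)
        assert deviation_z(fit, mean, x0)[0] == pytest.approx(0.0, abs=1e-12)
        y2 = mean + 2 * np.sqrt(var)
        assert deviation_z(fit, y2, x0)[0] == pytest.approx(2.0, abs=1e-12)

    def test_tail_rate_on_generative_data(self, rng):
        n = 4000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([0.2, 1.0]) + rng.normal(size=n)
        fit = fit_blr(y[:2000], X[:2000])
        z = deviation_z(fit, y[2000:], X[2000:])
        assert (np.abs(z) >= 2).mean() == pytest.approx(0.0455, abs=0.01)


class TestEvaluate:
    def test_perfect_prediction(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = X @ np.array([1.0, 2.0])
        fit = fit_blr(y, X)
        m = evaluate(fit, y, X)
        assert m.explained_variance == pytest.approx(1.0, abs=1e-6)
        assert m.smse == pytest.approx(0.0, abs=1e-6)

    def test_training_moment_prediction_is_reference(self, rng):
        # a model forced to predict the training mean: SMSE -> 1, MSLL -> 0
        n = 5000
        y = rng.normal(3.0, 1.5, n)
        X = np.ones((n, 1))
        fit = BLRFit(
            weights=np.array([y[: n // 2].mean()]),
            weight_cov=np.zeros((1, 1)),
            noise_precision=1.0 / y[: n // 2].var(ddof=1),
            train_mean=float(y[: n // 2].mean()),
            train_var=float(y[: n // 2].var(ddof=1)),
        )
        m = evaluate(fit, y[n // 2 :], X[n // 2 :])
        assert m.smse == pytest.approx(1.0, abs=0.05)
        assert m.msll == pytest.approx(0.0, abs=0.05)

    def test_ev_matches_independent_formula(self, rng):
        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        y = X @ np.array([1.0, 1.0]) + rng.normal(size=200)
        fit = fit_blr(y, X)
        m = evaluate(fit, y, X)
        mean, _ = predict(fit, X)
        ev_hand = 1.0 - np.var(y - mean) / np.var(y)
        assert m.explained_variance == pytest.approx(ev_hand, abs=1e-12)


class TestCohortModels:
    def test_calibration_on_heldout_controls(self, control_cohort):
        cov, profile, _ = control_cohort
        train, test = split_cohort(cov, 0.9, seed=11)
        ms = fit_normative_models(profile, cov, train)
        dev = score_deviations(ms, profile, cov, test)
        Z = dev.matrix()
        assert abs(Z.mean()) < 0.1
        assert 0.9 < Z.std() < 1.1

    def test_mean_function_recovery(self, control_cohort):
        cov, profile, truth = control_cohort
        train, _ = split_cohort(cov, 0.9, seed=12)
        ms = fit_normative_models(profile, cov, train, use_yeo_johnson=False)
        ages = np.linspace(*truth.age_range, 50)
        grid_cov = cov.iloc[:50].copy()
        grid_cov["age"] = ages
        grid_cov["sex"] = 0
        grid_cov["site"] = 0
        X = ms.design.matrix(grid_cov)
        for r, m in [(0, 0), (2, 1)]:
            mean, _ = predict(ms.fits[(r, m)], X)
            true_mean = truth.mean_function(r, m, ages, 0, 0)
            rmse = np.sqrt(np.mean((mean - true_mean) ** 2))
            assert rmse < 0.15 * truth.noise_sd[m]

    def test_crossval_partition_and_distribution(self, control_cohort):
        cov, profile, _ = control_cohort
        dev = crossval_control_deviations(profile, cov, k=10, seed=13)
        assert len(dev.subject_ids) == (cov["group"] == "control").sum()
        assert np.isfinite(dev.Z).all()
        z = dev.Z[:, 0, 0]
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_too_many_folds_rejected(self, control_cohort):
        cov, profile, _ = control_cohort
        with pytest.raises(ValueError):
            crossval_control_deviations(profile, cov, k=10_000)

    def test_outlier_rule(self):
        dev = normative.DeviationMatrix(
            ["a", "b"], ["r0"], np.array([[[0.5, 1.0, 8.0]], [[0.1, 0.2, 0.3]]])
        )
        retained, keep = exclude_outliers(dev)
        assert list(retained.subject_ids) == ["b"]
        assert np.all(np.abs(retained.matrix()) <= 7)


class TestTransfer:
    def _reference_fit(self, rng, n=1000):
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        w = np.array([0.5, 1.0])
        y = X @ w + rng.normal(0, 0.8, n)
        return fit_blr(y, X), X, w

    def test_no_shift_recovers_identity(self, rng):
        fit, X, w = self._reference_fit(rng)
        Xa = np.column_stack([np.ones(200), rng.normal(size=200)])
        ya = Xa @ w + rng.normal(0, 0.8, 200)
        re = transfer_recalibrate(fit, ya, Xa)
        assert abs(re.site_offset) < 3 * re.offset_se
        assert re.site_scale == pytest.approx(1.0, abs=0.15)

    def test_planted_shift_recovered(self, rng):
        fit, X, w = self._reference_fit(rng)
        delta = 1.0
        Xa = np.column_stack([np.ones(300), rng.normal(size=300)])
        ya = Xa @ w + delta + rng.normal(0, 0.8, 300)
        re = transfer_recalibrate(fit, ya, Xa)
        assert abs(re.site_offset - delta) < 3 * re.offset_se

    def test_recalibrated_tail_rate(self, rng):
        fit, X, w = self._reference_fit(rng)
        Xa = np.column_stack([np.ones(2000), rng.normal(size=2000)])
        ya = Xa @ w + 1.0 + rng.normal(0, 0.8, 2000)
        re = transfer_recalibrate(fit, ya[:500], Xa[:500])
        z = deviation_z(re, ya[500:], Xa[500:])
        assert (np.abs(z) >= 2).mean() == pytest.approx(0.0455, abs=0.015)

    def test_small_adaptation_sample_warns(self, rng):
        fit, X, w = self._reference_fit(rng, n=100)
        with pytest.warns(UserWarning):
            transfer_recalibrate(fit, np.ones(5), np.column_stack([np.ones(5), np.zeros(5)]))


class TestSitePredictability:
    def test_chance_level_for_exchangeable_sites(self, rng):
        Z = rng.normal(size=(200, 12))
        dev = normative.DeviationMatrix(
            [f"s{i}" for i in range(200)], [f"r{i}" for i in range(4)],
            Z.reshape(200, 4, 3),
        )
        acc = site_predictability_check(dev, rng.integers(0, 2, 200), seed=3)
        assert acc == pytest.approx(0.5, abs=0.1)

    def test_planted_site_offset_detected(self, rng):
        Z = rng.normal(size=(200, 12))
        sites = np.r_[np.zeros(100, int), np.ones(100, int)]
        Z[sites == 1] += 1.5
        dev = normative.DeviationMatrix(
            [f"s{i}" for i in range(200)], [f"r{i}" for i in range(4)],
            Z.reshape(200, 4, 3),
        )
        assert site_predictability_check(dev, sites, seed=4) > 0.7

    def test_single_site_is_nan(self, rng):
        dev = normative.DeviationMatrix(
            ["a", "b"], ["r"], rng.normal(size=(2, 1, 3))
        )
        assert np.isnan(site_predictability_check(dev, np.zeros(2, int)))
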