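import numpy as np
import pytest
from scipy import stats

from lesionmap import (
    DesignSpec,
    default_spec,
    fit_voxelwise_glm,
    lesion_t_map,
    null_cohort,
    simulate_cohort,
)
from lesionmap import testable_voxel_mask as voxel_mask_fn

from conftest import make_cohort, make_table, random_cohort, random_table


def brute_force_ols(X, y):
    """Independent oracle: full pseudo-inverse OLS with classical t-stats."""
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    mse = resid @ resid / df
    cov = mse * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return beta, mse, beta / se, df


class TestTestableMask:
    def test_threshold_definition(self):
        n = 20
        lesions = np.zeros((4, n), dtype=np.uint8)
        lesions[0, :5] = 1    # exactly 5 lesioned -> testable
        lesions[1, :4] = 1    # 4 lesioned -> not testable
        lesions[2, :16] = 1   # 4 non-lesioned -> not testable
        lesions[3, :15] = 1   # 5 non-lesioned -> testable
        cohort = make_cohort(lesions, pad=True)
        mask = voxel_mask_fn(cohort, DesignSpec())
        assert list(mask[:4]) == [True, False, False, True]
        assert not mask[4:].any()  # padding voxels have a single lesion

    def test_all_or_none_lesioned_untestable(self):
        n = 12
        lesions = np.zeros((3, n), dtype=np.uint8)
        lesions[0] = 1           # lesioned in all -> untestable
        lesions[1, :6] = 1
        cohort = make_cohort(lesions)  # voxel 2 lesioned in none
        mask = voxel_mask_fn(cohort, DesignSpec(min_lesion_count=1,
                                                min_nonlesion_count=1))
        assert list(mask) == [False, True, False]

    def test_empty_mask_warns(self):
        lesions = np.zeros((2, 6), dtype=np.uint8)
        lesions[0, :2] = 1
        lesions[1, 2:4] = 1
        cohort = make_cohort(lesions, pad=True)
        with pytest.warns(UserWarning, match="no testable voxels"):
            mask = voxel_mask_fn(cohort, DesignSpec())
        assert not mask.any()


class TestAgainstOracles:
    def test_lesion_only_model_equals_pooled_two_sample_t(self, rng):
        """With no covariates the lesion t is the classic pooled-variance
        two-sample t comparing lesioned vs spared outcomes."""
        cohort = random_cohort(rng, n_voxels=30, n_subjects=24)
        table = random_table(cohort, rng)
        spec = DesignSpec(covariates=())
        fit = fit_voxelwise_glm(cohort, table, spec)
        y = table.outcome()
        for k, v in enumerate(fit.voxel_idx):
            g1 = y[cohort.lesions[v] == 1]
            g0 = y[cohort.lesions[v] == 0]
            expected = stats.ttest_ind(g1, g0, equal_var=True).statistic
            assert fit.lesion_t[k] == pytest.approx(expected, abs=1e-10)

    def test_deterministic_covariate_relationship_recovered(self, rng):
        """Outcome = 2*age exactly: age beta is 2, lesion effect ~0."""
        cohort = random_cohort(rng, n_voxels=20, n_subjects=40)
        age = rng.normal(70, 10, 40)
        table = make_table(cohort, age, rng.lognormal(3, 0.4, 40),
                           rng.uniform(18, 168, 40), 2.0 * age)
        fit = fit_voxelwise_glm(cohort, table)
        np.testing.assert_allclose(fit.coef_for("age"), 2.0, atol=1e-8)
        np.testing.assert_allclose(fit.coef_for("lesion"), 0.0, atol=1e-8)

    def test_full_fit_matches_brute_force_on_random_instance(self, rng):
        """Coefficients, MSE and t equal an independent pinv solve at 1e-8
        on every voxel of a 100-voxel random cohort."""
        cohort = random_cohort(rng, n_voxels=100, n_subjects=40)
        table = random_table(cohort, rng)
        fit = fit_voxelwise_glm(cohort, table)
        X_cov = table.covariate_matrix()
        y = table.outcome()
        assert fit.voxel_idx.size == 100
        for k, v in enumerate(fit.voxel_idx):
            X = np.column_stack([np.ones(40), cohort.lesions[v], X_cov])
            beta, mse, tvals, df = brute_force_ols(X, y)
            assert df == fit.df
            assert fit.intercept[k] == pytest.approx(beta[0], abs=1e-8)
            assert fit.coef[k, 0] == pytest.approx(beta[1], abs=1e-8)
            np.testing.assert_allclose(fit.coef[k, 1:], beta[2:], atol=1e-8)
            assert fit.mse[k] == pytest.approx(mse, abs=1e-8)
            assert fit.lesion_t[k] == pytest.approx(tvals[1], abs=1e-8)

    def test_eight_subject_hand_instance(self):
        """Small instance checked against the normal-equations oracle to 1e-10."""
        lesions = np.array(
            [[1, 1, 1, 1, 0, 0, 0, 0],
             [1, 0, 1, 0, 1, 0, 1, 0]], dtype=np.uint8)
        cohort = make_cohort(lesions, pad=True)
        age = np.array([60.0, 72.0, 55.0, 80.0, 66.0, 71.0, 58.0, 64.0])
        vol = np.array([10.0, 40.0, 25.0, 5.0, 30.0, 12.0, 22.0, 18.0])
        fup = np.array([24.0, 100.0, 48.0, 72.0, 30.0, 150.0, 60.0, 90.0])
        y = np.array([12.0, 20.0, 9.0, 15.0, 4.0, 7.0, 6.0, 3.0])
        table = make_table(cohort, age, vol, fup, y)
        spec = DesignSpec(min_lesion_count=2, min_nonlesion_count=2)
        fit = fit_voxelwise_glm(cohort, table, spec)
        for k, v in enumerate(fit.voxel_idx):
            X = np.column_stack([np.ones(8), cohort.lesions[v], age, vol, fup])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            mse = resid @ resid / (8 - 5)
            se1 = np.sqrt(mse * np.linalg.inv(X.T @ X)[1, 1])
            assert fit.coef[k, 0] == pytest.approx(beta[1], abs=1e-10)
            assert fit.mse[k] == pytest.approx(mse, abs=1e-10)
            assert fit.lesion_t[k] == pytest.approx(beta[1] / se1, abs=1e-10)


class TestModelBehaviour:
    def test_deficit_increasing_lesions_give_positive_t(self):
        spec = default_spec(n_subjects=222, seed=6)
        cohort, table, truth = simulate_cohort(spec)
        fit = fit_voxelwise_glm(cohort, table)
        in_region = np.isin(fit.voxel_idx, np.flatnonzero(truth.gamma_map > 0))
        assert in_region.any()
        assert fit.lesion_t[in_region].mean() > 0
        assert fit.lesion_t[in_region].max() > fit.lesion_t[~in_region].max()

    def test_junk_covariate_barely_moves_lesion_t(self, rng):
        """Adding a pure-noise covariate changes high-SNR lesion t by <10%."""
        spec = default_spec(n_subjects=222, seed=13)
        cohort, table, truth = simulate_cohort(spec)
        fit = fit_voxelwise_glm(cohort, table)
        noisy = table.data.copy()
        noisy["junk"] = rng.normal(size=len(noisy))
        from lesionmap import CovariateTable

        table2 = CovariateTable(noisy)
        spec2 = DesignSpec(covariates=("age", "lesion_volume",
                                       "followup_time", "junk"))
        fit2 = fit_voxelwise_glm(cohort, table2, spec2)
        strong = fit.lesion_t > 3
        assert strong.any()
        rel = np.abs(fit2.lesion_t[strong] - fit.lesion_t[strong]) / np.abs(
            fit.lesion_t[strong]
        )
        assert rel.max() < 0.10

    def test_rank_deficient_voxel_dropped(self):
        """A lesion column identical to a covariate pattern is untestable."""
        n = 12
        lesions = np.zeros((3, n), dtype=np.uint8)
        lesions[0, :6] = 1
        lesions[1, ::2] = 1
        lesions[2, :5] = 1
        cohort = make_cohort(lesions, pad=True)
        binary_cov = lesions[0].astype(float)  # equals voxel 0's lesion column
        fup = 20.0 + 10.0 * (np.arange(n) % 5) + np.arange(n) ** 1.5
        table = make_table(cohort, binary_cov + 60, np.arange(n) + 1.0,
                           fup, np.arange(n, dtype=float))
        spec = DesignSpec(min_lesion_count=2, min_nonlesion_count=2)
        fit = fit_voxelwise_glm(cohort, table, spec)
        assert fit.n_dropped == 1
        assert 0 not in fit.voxel_idx

    def test_interaction_terms_added_and_fitted(self, rng):
        cohort = random_cohort(rng, n_voxels=10, n_subjects=50)
        table = random_table(cohort, rng)
        spec = DesignSpec(include_interactions=True)
        fit = fit_voxelwise_glm(cohort, table, spec)
        assert "age*lesion_volume" in fit.term_names
        assert "lesion_volume*followup_time" in fit.term_names
        y = table.outcome()
        X_cov = table.covariate_matrix()
        v = fit.voxel_idx[0]
        X = np.column_stack([
            np.ones(50), cohort.lesions[v], X_cov,
            X_cov[:, 0] * X_cov[:, 1], X_cov[:, 1] * X_cov[:, 2],
        ])
        beta = np.linalg.pinv(X) @ y
        assert fit.coef[0, 0] == pytest.approx(beta[1], abs=1e-8)
        np.testing.assert_allclose(fit.coef[0, 1:], beta[2:], atol=1e-8)

    def test_null_cohort_t_centered_at_zero(self):
        from lesionmap.synthetic import fwer_null_spec

        cohort, table, _ = null_cohort(fwer_null_spec(21))
        fit = fit_voxelwise_glm(cohort, table)
        t = fit.lesion_t
        assert t.size > 400
        assert abs(t.mean()) < 3 * t.std(ddof=1) / np.sqrt(t.size)

    def test_eloquence_map_extracts_t(self, rng):
        cohort = random_cohort(rng, n_voxels=5, n_subjects=30)
        table = random_table(cohort, rng)
        fit = fit_voxelwise_glm(cohort, table)
        emap = lesion_t_map(fit)
        np.testing.assert_array_equal(emap.t, fit.lesion_t)
        assert emap.threshold is None
        with pytest.raises(ValueError, match="threshold"):
            emap.surviving_mask
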