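"""Design construction, GLS fitting and linear contrasts."""

import numpy as np
import pytest

from vapbench.group_data import GroupRecord
from vapbench.logit_core import logit_proportion
from vapbench.meta_regression import (
    ModelSpec,
    build_design,
    fit_meta_regression,
    fit_to_dataframe,
    linear_contrast,
    run_model,
    standard_model,
)
from vapbench.random_effects import pool_random_effects


class TestStandardModels:
    def test_simple_models_have_series_terms_only(self):
        assert standard_model(1).moderators == ()
        assert standard_model(4).arm_scope == "intervention"

    def test_full_models_add_three_covariates(self):
        assert len(standard_model(2).moderators) == 3
        assert standard_model(5).moderators == standard_model(2).moderators

    def test_quality_restriction_on_models_3_and_6(self):
        assert standard_model(3).quality_restricted
        assert standard_model(6).quality_restricted
        assert not standard_model(2).quality_restricted

    def test_invalid_id_rejected(self):
        with pytest.raises(ValueError):
            standard_model(7)


class TestBuildDesign:
    def test_benchmark_only_gives_intercept_column(self, toy_groups):
        bench = [g for g in toy_groups if g.arm_role == "benchmark"]
        y, v, x, names, used = build_design(bench, standard_model(1))
        assert x.shape == (3, 1)
        assert names == ("benchmark_reference",)
        assert np.all(x == 1.0)

    def test_full_model_adds_exactly_three_columns(self, toy_groups):
        _, _, x1, _, _ = build_design(toy_groups, standard_model(1))
        _, _, x2, _, _ = build_design(toy_groups, standard_model(2))
        assert x2.shape[1] == x1.shape[1] + 3

    def test_duplex_is_annotation_not_a_term(self, toy_groups):
        _, _, _, names, _ = build_design(toy_groups, standard_model(2))
        assert "duplex" not in names

    def test_quality_restriction_keeps_all_benchmark(self, toy_groups):
        _, _, _, _, used = build_design(toy_groups, standard_model(3))
        assert sum(g.arm_role == "benchmark" for g in used) == 3
        assert all(
            g.quality_majority is True
            for g in used if g.arm_role != "benchmark"
        )

    def test_missing_covariates_dropped_by_default(self, toy_groups):
        # s2 has unknown mv_lt90 and must be excluded from full models
        _, _, _, _, used = build_design(toy_groups, standard_model(2))
        assert "s2" not in {g.study_id for g in used}

    def test_missing_covariates_error_mode_names_groups(self, toy_groups):
        with pytest.raises(ValueError, match="s2"):
            build_design(toy_groups, standard_model(2), on_missing="error")

    def test_response_is_group_logit(self, toy_groups):
        y, v, _, _, used = build_design(toy_groups, standard_model(1))
        expected = logit_proportion(used[0].events, used[0].denominator)
        assert y[0] == pytest.approx(expected.logit_value)
        assert v[0] == pytest.approx(expected.variance)


class TestFit:
    def make_data(self, seed=3, k=40):
        rng = np.random.default_rng(seed)
        x = np.column_stack([np.ones(k), rng.integers(0, 2, k).astype(float)])
        v = 0.05 + rng.random(k) * 0.1
        beta = np.array([-1.26, 0.67])
        y = x @ beta + rng.normal(0, np.sqrt(v + 0.3))
        return y, v, x

    def test_intercept_only_reproduces_pooling(self):
        y, v, _ = self.make_data()
        estimates = [
            logit_proportion(1, 2)  # placeholder, replaced below
        ]
        from vapbench.logit_core import LogitEstimate

        estimates = [
            LogitEstimate(a, b, 0, 1) for a, b in zip(y, v)
        ]
        pooled = pool_random_effects(estimates, tau2_method="reml")
        fit = fit_meta_regression(y, v, np.ones((len(y), 1)),
                                  tau2_method="reml")
        assert fit.beta[0] == pytest.approx(pooled.mu_logit, abs=1e-6)
        assert fit.tau2_resid == pytest.approx(pooled.tau2, abs=1e-6)

    def test_zero_tau2_equals_closed_form_wls(self):
        # response exactly linear in the design: residual heterogeneity 0
        k = 12
        x = np.column_stack([np.ones(k), np.arange(k, dtype=float)])
        v = np.linspace(0.05, 0.3, k)
        y = -1.0 + 0.1 * np.arange(k)
        fit = fit_meta_regression(y, v, x, tau2_method="mm")
        assert fit.tau2_resid == 0.0
        w = np.diag(1.0 / v)
        beta_wls = np.linalg.solve(x.T @ w @ x, x.T @ w @ y)
        assert fit.beta == pytest.approx(beta_wls, abs=1e-10)

    @pytest.mark.parametrize("method", ["reml", "mm"])
    def test_row_permutation_invariance(self, method):
        y, v, x = self.make_data()
        perm = np.random.default_rng(0).permutation(len(y))
        fit1 = fit_meta_regression(y, v, x, tau2_method=method)
        fit2 = fit_meta_regression(y[perm], v[perm], x[perm], tau2_method=method)
        assert fit1.beta == pytest.approx(fit2.beta, abs=1e-8)
        assert fit1.tau2_resid == pytest.approx(fit2.tau2_resid, abs=1e-8)

    def test_singular_design_names_collinear_columns(self):
        y, v, x = self.make_data()
        x = np.column_stack([x, x[:, 1]])
        with pytest.raises(ValueError, match="collinear.*x2"):
            fit_meta_regression(y, v, x)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_meta_regression(np.zeros(3), np.ones(3), np.ones((3, 2)))

    def test_cov_symmetric_psd(self):
        y, v, x = self.make_data()
        fit = fit_meta_regression(y, v, x)
        assert np.allclose(fit.cov, fit.cov.T)
        assert np.all(np.linalg.eigvalsh(fit.cov) > 0)

    def test_run_model_on_mixed_groups(self, toy_groups):
        fit = run_model(toy_groups, standard_model(1, tau2_method="mm"))
        assert fit.k == 6  # 3 benchmark + 3 control arms; interventions excluded
        frame = fit_to_dataframe(fit)
        assert list(frame.columns) == ["factor", "coefficient", "ci_low",
                                       "ci_high", "p"]


class TestContrast:
    def fit(self):
        rng = np.random.default_rng(8)
        k = 30
        x = np.column_stack([
            np.ones(k),
            (np.arange(k) % 3 == 1).astype(float),
            (np.arange(k) % 3 == 2).astype(float),
        ])
        v = np.full(k, 0.1)
        y = x @ np.array([-1.26, -0.1, 0.67]) + rng.normal(0, 0.5, k)
        return fit_meta_regression(y, v, x, tau2_method="mm")

    def test_unit_vector_reproduces_coefficient(self):
        fit = self.fit()
        res = linear_contrast(fit, [0.0, 0.0, 1.0])
        assert res.estimate == pytest.approx(fit.beta[2])
        assert res.p == pytest.approx(fit.p_values[2])
        assert res.ci == pytest.approx(tuple(fit.ci[2]))

    def test_series_difference_contrast(self):
        fit = self.fit()
        res = linear_contrast(fit, [0.0, -1.0, 1.0])
        assert res.estimate == pytest.approx(fit.beta[2] - fit.beta[1])

    def test_zero_vector_gives_null_result(self):
        res = linear_contrast(self.fit(), [0.0, 0.0, 0.0])
        assert res.estimate == 0.0
        assert res.p == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            linear_contrast(self.fit(), [1.0, 0.0])
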