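"""Quadratic response-surface fitting, ANOVA/lack-of-fit and diagnostics."""

import numpy as np
import pytest

import assayopt as ao


def _loo_press(design, y_work):
    """Brute-force leave-one-out PRESS: refit without each run in turn."""
    X = ao.build_model_matrix(design).to_numpy()
    press = 0.0
    for i in range(len(y_work)):
        keep = np.arange(len(y_work)) != i
        beta, *_ = np.linalg.lstsq(X[keep], y_work[keep], rcond=None)
        press += (y_work[i] - X[i] @ beta) ** 2
    return press


class TestModelMatrix:
    def test_term_count_and_order(self, reference_design):
        design, _ = reference_design
        X = ao.build_model_matrix(design)
        assert list(X.columns) == [
            "1", "temperature", "time", "volume",
            "temperature:time", "temperature:volume", "time:volume",
            "temperature^2", "time^2", "volume^2",
        ]

    def test_center_and_axial_rows(self, reference_design):
        design, _ = reference_design
        X = ao.build_model_matrix(design).to_numpy()
        centers = [i for i, p in enumerate(design.runs) if p.point_class == "center"]
        assert np.allclose(X[centers][:, 1:], 0.0)
        assert np.allclose(X[centers][:, 0], 1.0)
        a = 2 ** 0.75
        i_ax = next(i for i, p in enumerate(design.runs)
                    if p.point_class == "axial" and p.coded[0] > 1)
        row = X[i_ax]
        assert row[1] == pytest.approx(a)
        assert row[7] == pytest.approx(a * a)  # = 2**1.5 ≈ 2.8284
        assert np.allclose(np.delete(row, [0, 1, 7]), 0.0)

    def test_rank_deficiency_detected(self, reference_factors):
        small = ao.design_from_coded(
            reference_factors, [(0, 0, 0)] * 5)
        with pytest.raises(ao.FitError):
            ao.build_model_matrix(small)


class TestFit:
    def test_constant_response_gives_pure_intercept(self, reference_design):
        design, _ = reference_design
        res = ao.ResponseSurfaceModel(design, np.full(18, 123.0), "ln").fit()
        assert res.params["1"] == pytest.approx(np.log(123.0), abs=1e-10)
        assert np.allclose(res.params.drop("1"), 0.0, atol=1e-10)

    def test_noise_free_truth_recovered(self, reference_design):
        design, _ = reference_design
        truth = ao.TrueSurface(noise_sd_ln=0.0)
        y = ao.simulate_surface(truth, design, seed=1)
        res = ao.ResponseSurfaceModel(design, y, "ln").fit()
        for term, b in truth.coefficients.items():
            assert res.params[term] == pytest.approx(b, abs=1e-8)

    def test_nonpositive_response_under_ln_rejected(self, reference_design):
        design, y = reference_design
        y = y.copy()
        y[0] = 0.0
        with pytest.raises(ao.FitError):
            ao.ResponseSurfaceModel(design, y, "ln")

    def test_residuals_orthogonal_to_model_columns(self, reference_fit):
        X = reference_fit.model.exog.to_numpy()
        y_norm = np.linalg.norm(reference_fit.model.y_work)
        assert np.max(np.abs(X.T @ reference_fit.resid)) < 1e-8 * y_norm


class TestAnovaLackOfFit:
    def test_partition_additivity(self, reference_fit):
        an = reference_fit.anova_lof()
        assert an.ss_total == pytest.approx(an.ss_model + an.ss_residual,
                                            rel=1e-8)
        assert an.ss_residual == pytest.approx(
            an.ss_lack_of_fit + an.ss_pure_error, rel=1e-8)
        assert an.df_total == an.df_model + an.df_residual
        assert an.df_residual == an.df_lack_of_fit + an.df_pure_error

    def test_exact_quadratic_has_zero_lack_of_fit(self, reference_design):
        design, _ = reference_design
        truth = ao.TrueSurface(noise_sd_ln=0.0)
        # perturb centre replicates identically so pure error stays 0 too
        y = ao.simulate_surface(truth, design, seed=0)
        an = ao.ResponseSurfaceModel(design, y, "ln").fit().anova_lof()
        assert an.ss_residual == pytest.approx(0.0, abs=1e-16)
        assert an.ss_lack_of_fit == pytest.approx(0.0, abs=1e-16)

    def test_partition_matches_longhand_on_small_design(self, rng):
        factors = [ao.make_factor("a", "", -1, 1), ao.make_factor("b", "", -1, 1)]
        design = ao.build_ccd(factors, n_center=3, alpha=ao.rotatable_alpha(2))
        y = rng.normal(5.0, 1.0, design.n_runs)
        res = ao.ResponseSurfaceModel(design, y, "none").fit()
        an = res.anova_lof()
        # longhand pure error over the three centre replicates
        centers = [i for i, p in enumerate(design.runs)
                   if p.point_class == "center"]
        yc = y[centers]
        ss_pe = float(np.sum((yc - yc.mean()) ** 2))
        assert an.ss_pure_error == pytest.approx(ss_pe, rel=1e-10)
        assert an.df_pure_error == 2
        ss_res = float(res.resid @ res.resid)
        assert an.ss_lack_of_fit == pytest.approx(ss_res - ss_pe, rel=1e-8)

    def test_no_replicates_raises_but_plain_table_available(self, reference_factors):
        design = ao.build_ccd(reference_factors, n_center=1)
        y = np.exp(ao.TrueSurface(noise_sd_ln=0.0).linear_predictor(design))
        y *= np.exp(np.linspace(0, 0.2, design.n_runs))  # break the exact fit
        res = ao.ResponseSurfaceModel(design, y, "ln").fit()
        with pytest.raises(ao.FitError):
            res.anova_lof()
        an = res.anova_lof(require_replicates=False)
        assert an.ss_lack_of_fit is None and an.p_model >= 0


class TestDiagnostics:
    def test_press_equals_brute_force_loo(self, reference_fit, reference_design):
        design, _ = reference_design
        dg = reference_fit.diagnostics()
        assert dg.press == pytest.approx(
            _loo_press(design, reference_fit.model.y_work), rel=1e-8)

    def test_press_loo_equivalence_on_random_data(self, rng, reference_design):
        design, _ = reference_design
        for _ in range(5):
            y = rng.normal(10.0, 1.0, design.n_runs)
            res = ao.ResponseSurfaceModel(design, y, "none").fit()
            assert res.diagnostics().press == pytest.approx(
                _loo_press(design, y), rel=1e-8)

    def test_r2_orderings(self, rng, reference_design):
        design, _ = reference_design
        for _ in range(5):
            y = rng.normal(10.0, 1.0, design.n_runs)
            dg = ao.ResponseSurfaceModel(design, y, "none").fit().diagnostics()
            assert dg.adj_r2 <= dg.r2 + 1e-12
            assert dg.pred_r2 <= dg.r2 + 1e-12
            assert dg.press >= 0

    def test_near_perfect_fit_r2_one(self, reference_design):
        design, _ = reference_design
        y = ao.simulate_surface(ao.TrueSurface(noise_sd_ln=0.0), design, seed=0)
        dg = ao.ResponseSurfaceModel(design, y, "ln").fit().diagnostics()
        assert dg.r2 == pytest.approx(1.0, abs=1e-10)
        assert dg.pred_r2 == pytest.approx(1.0, abs=1e-8)


class TestCoefficientTests:
    def test_t_matches_longhand_ratio(self, reference_fit):
        ct = reference_fit.coefficient_tests()
        assert np.allclose(ct["t"], ct["coef"] / ct["se"])

    def test_star_thresholds(self):
        assert ao.significance_stars(0.0005) == "***"
        assert ao.significance_stars(0.005) == "**"
        assert ao.significance_stars(0.05) == ""

    def test_zero_residual_variance_rejected(self, reference_design):
        design, _ = reference_design
        y = np.exp(ao.TrueSurface(noise_sd_ln=0.0).linear_predictor(design))
        # exact surface through replicated centres -> zero residual variance
        res = ao.ResponseSurfaceModel(design, y, "ln").fit()
        with pytest.raises(ao.FitError):
            res.coefficient_tests()


class TestPredict:
    def test_back_transform_consistency(self, reference_fit):
        ln_val = reference_fit.predict(actual=[61, 60, 80], back_transform=False)
        assert reference_fit.predict(actual=[61, 60, 80]) == pytest.approx(
            np.exp(ln_val))

    def test_exact_surface_interpolates_design_points(self, reference_design):
        design, _ = reference_design
        y = ao.simulate_surface(ao.TrueSurface(noise_sd_ln=0.0), design, seed=0)
        res = ao.ResponseSurfaceModel(design, y, "ln").fit()
        preds = res.predict(coded=design.coded_matrix)
        assert np.allclose(preds, y, rtol=1e-8)

    def test_dimension_mismatch(self, reference_fit):
        with pytest.raises(ao.DesignError):
            reference_fit.predict(actual=[61, 60])

    def test_coverage_of_coefficient_cis_under_noise(self, reference_design):
        """95% CIs cover the generating truth at close to nominal rate."""
        design, _ = reference_design
        truth = ao.TrueSurface(noise_sd_ln=0.15)
        beta = truth.coefficients
        n_rep = 400
        covered = 0
        total = 0
        for rep in range(n_rep):
            y = ao.simulate_surface(truth, design, seed=10_000 + rep)
            res = ao.ResponseSurfaceModel(design, y, "ln").fit()
            ci = res.conf_int(0.05)
            for term in res.params.index:
                total += 1
                if ci.loc[term, "lower"] <= beta[term] <= ci.loc[term, "upper"]:
                    covered += 1
        assert covered / total == pytest.approx(0.95, abs=0.05)
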