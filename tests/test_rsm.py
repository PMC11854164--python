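"""Quadratic response-surface fit, ANOVA, diagnostics and optimization.

The frozen expected values are the reference study's printed numbers where
those are internally consistent, and independently recomputed values where
the printed equation carries documented misprints (the signs of the AB/AC
interactions and the digits of the B-squared coefficient do not reproduce
the printed predicted column; the least-squares values do).
"""

import math

import numpy as np
import pytest

from yieldsurf.design import build_bbd, code
from yieldsurf.rsm import (
    SingularFitError,
    anova,
    diagnostics,
    fit_quadratic,
    model_matrix,
    optimize_surface,
    perturbation_curves,
    predict,
    r_squared,
)
from yieldsurf.synthdata import SurfaceTruth, generate

# least-squares coefficients; AB/AC signs and the B2 digits deviate from the
# misprinted reference equation but reproduce its predicted column exactly
EXPECTED_COEF = [27.522, 4.575, 1.95, 1.665, -0.730, -1.660, -0.170, -7.681, -3.551, -3.341]


class TestFit:
    def test_coefficients_match_reference(self, fitted):
        assert np.allclose(np.round(fitted.coef, 3), EXPECTED_COEF, atol=5e-4)

    def test_agrees_with_statsmodels_ols(self, bbd17, fitted):
        sm = pytest.importorskip("statsmodels.api")
        obs = bbd17.dataset.observed()
        res = sm.OLS(obs.yields, model_matrix(obs.coded_matrix)).fit()
        assert np.allclose(fitted.coef, res.params, atol=1e-8)

    def test_intercept_is_center_mean(self, bbd17, fitted):
        centers = [
            p.observed_yield for p in bbd17.dataset.points if p.coded == (0, 0, 0)
        ]
        assert fitted.b0 == pytest.approx(np.mean(centers), abs=1e-9)

    def test_residuals_sum_to_zero_and_orthogonal(self, bbd17, fitted):
        assert abs(fitted.residuals.sum()) < 1e-9
        X = model_matrix(bbd17.dataset.coded_matrix)
        assert np.all(np.abs(X.T @ fitted.residuals) < 1e-8)

    def test_noise_free_recovery(self, surface_truth):
        truth = SurfaceTruth(surface_truth.coefficients, 0.0, surface_truth.factors)
        data = generate(truth, build_bbd(truth.factors, 5), seed=0)
        refit = fit_quadratic(data)
        assert np.allclose(refit.coef, truth.coefficients, atol=1e-9)

    def test_singular_design_names_columns(self, surface_truth):
        # every run has C = 0, so the C, AC, BC and C^2 columns collapse
        truth = SurfaceTruth(surface_truth.coefficients, 0.0, surface_truth.factors)
        ds = build_bbd(truth.factors, 5)
        flat = [p for p in ds.points if p.coded[2] == 0]
        ds = type(ds)(ds.factors, flat * 2)
        data = generate(truth, ds, seed=0)
        with pytest.raises(SingularFitError, match="C"):
            fit_quadratic(data)


class TestPredict:
    @pytest.mark.parametrize(
        "coded, expected",
        [((-1, -1, 0), 9.035), ((1, -1, 0), 19.645), ((-1, 0, -1), 8.6)],
    )
    def test_reference_rows(self, fitted, coded, expected):
        assert round(predict(fitted, coded), 3) == pytest.approx(expected, abs=5e-4)

    def test_full_predicted_column(self, bbd17, fitted):
        reported = bbd17.annotations["predicted_yield"]["values"]
        computed = predict(fitted, bbd17.dataset.coded_matrix)
        assert np.allclose(np.round(computed, 3), reported, atol=5e-4)

    def test_origin_gives_intercept(self, fitted):
        assert predict(fitted, (0, 0, 0)) == pytest.approx(fitted.b0)


class TestAnova:
    def test_reference_table(self, bbd17, fitted):
        table = anova(fitted, bbd17.dataset)
        # half a unit in the last printed digit
        assert table["Model"].f == pytest.approx(3.84, abs=0.0051)
        assert table["A"].ss == pytest.approx(167.45, abs=0.0051)
        assert table["A"].f == pytest.approx(9.41, abs=0.0051)
        assert table["A2"].ss == pytest.approx(248.41, abs=0.0051)
        assert table["B2"].ss == pytest.approx(53.09, abs=0.0051)
        assert table["BC"].ss == pytest.approx(0.1156, abs=0.000051)
        assert table["Pure Error"].ss == pytest.approx(38.08, abs=0.0051)
        assert table["Lack of Fit"].f == pytest.approx(3.03, abs=0.0051)
        assert table["Model"].signif == "*"

    def test_additivity_and_degrees_of_freedom(self, bbd17, fitted):
        table = anova(fitted, bbd17.dataset)
        assert table["Model"].ss + table["Residual"].ss == pytest.approx(
            table["Cor Total"].ss, abs=1e-6
        )
        assert table["Lack of Fit"].ss + table["Pure Error"].ss == pytest.approx(
            table["Residual"].ss, abs=1e-6
        )
        assert table["Model"].df == 9
        assert table["Cor Total"].df == 16
        assert table["Residual"].df == table["Lack of Fit"].df + table["Pure Error"].df

    def test_linear_term_closed_form(self, fitted, bbd17):
        """Type III SS of an orthogonal linear/interaction term is 8b² / 4b²."""
        table = anova(fitted, bbd17.dataset)
        assert table["A"].ss == pytest.approx(8 * fitted.coef[1] ** 2, abs=1e-9)
        assert table["AB"].ss == pytest.approx(4 * fitted.coef[4] ** 2, abs=1e-9)

    def test_quadratic_block_inverse_entry(self, fitted):
        """Diagonal of (X'X)^-1 for a squared term, against a direct inverse
        of the 4x4 intercept/quadratic block of the 17-run design."""
        block = np.array(
            [[17, 8, 8, 8], [8, 8, 4, 4], [8, 4, 8, 4], [8, 4, 4, 8]], dtype=float
        )
        c_qq = np.linalg.inv(block)[1, 1]
        assert round(c_qq, 4) == 0.2375
        assert fitted.xtx_inv[7, 7] == pytest.approx(c_qq, abs=1e-12)

    def test_perfect_fit_flags_infinite_f(self, surface_truth):
        truth = SurfaceTruth(surface_truth.coefficients, 0.0, surface_truth.factors)
        data = generate(truth, build_bbd(truth.factors, 5), seed=0)
        model = fit_quadratic(data)
        table = anova(model, data)
        assert table["Residual"].ss == pytest.approx(0, abs=1e-18)
        assert math.isinf(table["Model"].f)

    def test_no_replicates_warns_and_omits_lack_of_fit(self, surface_truth):
        data = generate(surface_truth, build_bbd(surface_truth.factors, 1), seed=3)
        model = fit_quadratic(data)
        with pytest.warns(UserWarning, match="lack-of-fit"):
            table = anova(model, data)
        with pytest.raises(KeyError):
            table["Lack of Fit"]

    def test_tsv_round_trip(self, bbd17, fitted, tmp_path):
        table = anova(fitted, bbd17.dataset)
        out = tmp_path / "anova.tsv"
        table.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[1].startswith("Model\t614.36\t9\t68.26\t3.84\t0.0451 *")
        assert lines[-1].startswith("Cor Total\t738.95\t16")


class TestRSquared:
    def test_reference_value_is_ss_ratio(self, bbd17, fitted):
        # 614.36 / 738.95; the reference prints 0.8358 for a dataset it
        # does not publish, so the SS-ratio definition is authoritative here
        assert r_squared(fitted, bbd17.dataset) == pytest.approx(0.8314, abs=5e-4)

    def test_perfect_fit(self, surface_truth):
        truth = SurfaceTruth(surface_truth.coefficients, 0.0, surface_truth.factors)
        data = generate(truth, build_bbd(truth.factors, 5), seed=0)
        assert r_squared(fit_quadratic(data), data) == pytest.approx(1.0)

    def test_zero_variance_signalled(self, surface_truth):
        flat = SurfaceTruth((20.0,) + (0.0,) * 9, 0.0, surface_truth.factors)
        data = generate(flat, build_bbd(flat.factors, 5), seed=0)
        with pytest.raises(ValueError, match="zero total"):
            r_squared(fit_quadratic(data), data)


class TestDiagnostics:
    def test_leverage_trace_equals_model_terms(self, bbd17, fitted):
        d = diagnostics(fitted, bbd17.dataset)
        assert d.leverage.sum() == pytest.approx(10.0, abs=1e-9)

    def test_center_replicates_share_leverage(self, bbd17, fitted):
        d = diagnostics(fitted, bbd17.dataset)
        assert np.ptp(d.leverage[12:]) < 1e-12

    def test_cooks_distance_nonnegative(self, bbd17, fitted):
        assert np.all(diagnostics(fitted, bbd17.dataset).cooks_d >= 0)

    def test_against_statsmodels_influence(self, bbd17, fitted):
        sm = pytest.importorskip("statsmodels.api")
        obs = bbd17.dataset.observed()
        res = sm.OLS(obs.yields, model_matrix(obs.coded_matrix)).fit()
        infl = res.get_influence()
        d = diagnostics(fitted, bbd17.dataset)
        assert np.allclose(d.leverage, infl.hat_matrix_diag, atol=1e-9)
        assert np.allclose(d.cooks_d, infl.cooks_distance[0], atol=1e-9)
        assert np.allclose(d.studentized, infl.resid_studentized_internal, atol=1e-9)


class TestPerturbation:
    def test_curves_pass_through_intercept(self, fitted):
        curves = perturbation_curves(fitted)
        for arr in curves.values():
            mid = arr[len(arr) // 2]
            assert mid[0] == pytest.approx(0.0)
            assert mid[1] == pytest.approx(fitted.b0)

    def test_curvature_sign_matches_quadratic_coef(self, fitted):
        arr = perturbation_curves(fitted)["A"][:, 1]
        second_diff = arr[2:] - 2 * arr[1:-1] + arr[:-2]
        assert np.all(np.sign(second_diff) == np.sign(fitted.coef[7]))

    def test_endpoints_equal_prediction(self, fitted):
        arr = perturbation_curves(fitted)["A"]
        assert arr[0, 1] == pytest.approx(predict(fitted, (-1, 0, 0)))
        assert arr[-1, 1] == pytest.approx(predict(fitted, (1, 0, 0)))


class TestOptimizeSurface:
    def test_reference_surface_interior_maximum(self, fitted):
        opt = optimize_surface(fitted)
        assert opt.kind == "interior-stationary"
        assert np.allclose(opt.coded_point, (0.267, 0.243, 0.177), atol=2e-3)
        assert opt.value == pytest.approx(28.52, abs=5e-3)

    def test_against_scipy_minimize(self, fitted):
        from scipy.optimize import minimize

        res = minimize(
            lambda x: -predict(fitted, x), x0=np.zeros(3), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12},
        )
        opt = optimize_surface(fitted)
        assert -res.fun == pytest.approx(opt.value, abs=1e-6)
        assert np.allclose(res.x, opt.coded_point, atol=1e-4)

    def test_against_grid_oracle(self, fitted):
        grid = np.linspace(-1, 1, 101)
        G = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), -1).reshape(-1, 3)
        vals = predict(fitted, G)
        opt = optimize_surface(fitted)
        assert opt.value >= vals.max() - 1e-3

    def test_linear_ridge_maximized_on_boundary(self, fitted):
        model = type(fitted)(
            coef=np.array([0.0, 2.0] + [0.0] * 8),
            n=fitted.n, fitted=fitted.fitted, residuals=fitted.residuals,
            xtx_inv=fitted.xtx_inv, coded=fitted.coded,
        )
        opt = optimize_surface(model)
        assert "singular" in opt.kind or "boundary" in opt.kind
        assert opt.coded_point[0] == pytest.approx(1.0, abs=1e-3)
        assert opt.value == pytest.approx(2.0, abs=1e-3)

    def test_saddle_falls_back_to_grid(self, fitted):
        coef = np.zeros(10)
        coef[7], coef[8] = 1.0, -1.0  # A^2 - B^2 saddle
        model = type(fitted)(
            coef=coef, n=fitted.n, fitted=fitted.fitted,
            residuals=fitted.residuals, xtx_inv=fitted.xtx_inv, coded=fitted.coded,
        )
        opt = optimize_surface(model)
        assert "saddle" in opt.kind or "boundary" in opt.kind
        assert opt.value == pytest.approx(1.0, abs=1e-3)
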