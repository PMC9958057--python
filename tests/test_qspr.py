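"""Curvilinear regression, diagnostics, screening and comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from rrqspr import (
    PolynomialQSPR,
    RegressionModel,
    avg_residual_percent,
    chi_square_gof,
    comparison_report,
    fit_polynomial,
    load_fixture,
    predict,
    rmse,
    select_best_models,
)
from rrqspr.datasets import PROPERTY_COLUMNS

RNG = np.random.default_rng(20230224)


class TestFitPolynomial:
    def test_exact_linear_data(self):
        x = np.arange(10.0)
        res = fit_polynomial(x, 2 * x + 1, 1)
        a1, gamma = res.params
        assert a1 == pytest.approx(2) and gamma == pytest.approx(1)
        assert res.rsquared == pytest.approx(1)

    def test_noise_free_parameter_recovery(self):
        """Linear and quadratic coefficients recover to 1e-6 as noise -> 0."""
        x = np.linspace(1, 6, 30)
        lin = fit_polynomial(x, 3.5 * x - 2.25, 1)
        assert lin.params == pytest.approx((3.5, -2.25), abs=1e-6)
        quad = fit_polynomial(x, -1.5 * x**2 + 4.0 * x + 7.0, 2)
        assert quad.params == pytest.approx((-1.5, 4.0, 7.0), abs=1e-6)

    def test_benzenoid_bp_fit_matches_published_coefficients(self, benzenoid_ti, benzenoid_properties):
        res = fit_polynomial(benzenoid_ti.to_numpy(), benzenoid_properties["BP"].to_numpy(), 1)
        a1, gamma = res.params
        assert round(a1) == 129 and round(gamma, 2) == -75.26
        assert round(res.rsquared, 4) == 0.9587

    def test_benzenoid_bp_quadratic_coefficients(self, benzenoid_ti, benzenoid_properties):
        res = fit_polynomial(benzenoid_ti.to_numpy(), benzenoid_properties["BP"].to_numpy(), 2)
        a1, a2, gamma = res.params
        assert round(a1, 2) == -10.47
        assert round(a2, 1) == 202.4
        assert round(gamma, 1) == -192.6

    def test_residuals_sum_to_zero(self, benzenoid_ti, benzenoid_properties):
        for deg in (1, 2):
            res = fit_polynomial(benzenoid_ti.to_numpy(), benzenoid_properties["BP"].to_numpy(), deg)
            assert abs(res.resid.sum()) < 1e-8 * abs(benzenoid_properties["BP"].sum())

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_polynomial([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0], 1)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            fit_polynomial([1.0, 2.0], [1.0, 2.0], 1)

    def test_from_dataframe_and_summary(self, benzenoid_ti, benzenoid_properties):
        df = benzenoid_properties.assign(TI=benzenoid_ti)
        res = PolynomialQSPR.from_dataframe(df, "BP", "TI", degree=1).fit()
        text = res.summary()
        assert "BP ~ TI" in text and "R^2" in text and "0.9587" in text


class TestPredict:
    def test_published_linear_model_at_benzene(self):
        rm = RegressionModel(1, alpha1=129, gamma=-75.26)
        assert predict(rm, 1.5) == pytest.approx(118.24)

    def test_published_quadratic_model_at_benzene(self):
        rm = RegressionModel(2, alpha1=-10.47, alpha2=202.4, gamma=-192.6)
        assert predict(rm, 1.5) == pytest.approx(87.4425)

    def test_zero_polynomial(self):
        rm = RegressionModel(1, alpha1=0.0, gamma=0.0)
        assert predict(rm, 123.4) == 0.0


class TestDiagnostics:
    def test_chi_square_trivial_cases(self):
        assert chi_square_gof([4.0], [2.0]) == pytest.approx(1.0)
        assert chi_square_gof([3.0, 5.0], [3.0, 5.0]) == 0.0

    def test_chi_square_rejects_nonpositive_observed(self):
        with pytest.raises(ValueError, match="positive"):
            chi_square_gof([0.0, 1.0], [1.0, 1.0])

    def test_avg_residual_percent(self):
        assert avg_residual_percent([100.0], [90.0]) == pytest.approx(10.0)
        assert avg_residual_percent([7.0, 9.0], [7.0, 9.0]) == 0.0

    def test_rmse_conventions(self):
        obs = np.array([3.0, 4.0])
        assert rmse(obs, np.zeros(2), "n") == pytest.approx(math.sqrt(12.5))
        assert rmse(obs, obs, "n") == 0.0
        assert rmse(obs, np.zeros(2), "n-p", p=1) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            rmse(obs, obs, "n-p", p=2)

    def test_permutation_invariance(self):
        obs = RNG.uniform(10, 100, size=26)
        pred = obs + RNG.normal(0, 3, size=26)
        perm = RNG.permutation(26)
        assert chi_square_gof(obs, pred) == pytest.approx(chi_square_gof(obs[perm], pred[perm]))
        assert avg_residual_percent(obs, pred) == pytest.approx(
            avg_residual_percent(obs[perm], pred[perm]))

    def test_published_bp_rmse_matches_n_minus_p_convention(self, benzenoid_ti, benzenoid_properties):
        """The published RMSE for the linear BP model (23.2957) is the
        sqrt(SSR/(n-p)) convention on published-coefficient predictions."""
        rm = RegressionModel(1, alpha1=129, gamma=-75.26)
        bp = benzenoid_properties["BP"].to_numpy()
        pred = rm.predict(benzenoid_ti.to_numpy())
        assert round(rmse(bp, pred, "n-p", p=2), 4) == 23.2957
        assert round(rmse(bp, pred, "n"), 4) == 22.3818


class TestNestedModels:
    def test_quadratic_r2_never_below_linear(self, benzenoid_ti, benzenoid_properties):
        """Nested-model monotonicity across all 12 packaged properties."""
        x = benzenoid_ti.to_numpy()
        for prop in PROPERTY_COLUMNS:
            y = benzenoid_properties[prop].to_numpy()
            r1 = fit_polynomial(x, y, 1).rsquared
            r2 = fit_polynomial(x, y, 2).rsquared
            assert r2 >= r1 - 1e-12


class TestSelection:
    def _props(self, y):
        return pd.DataFrame({"P": y})

    def test_single_good_index_selected(self):
        x = np.linspace(1, 5, 20)
        best = select_best_models(self._props(2 * x + RNG.normal(0, 0.01, 20)), {"TI": x}, 1)
        assert best["P"].selected and best["P"].results.regression_model.index_name == "TI"

    def test_below_threshold_flagged(self):
        x = np.linspace(1, 5, 40)
        noise = RNG.normal(0, 1, 40)  # essentially uncorrelated
        best = select_best_models(self._props(noise), {"TI": x}, 1)
        assert not best["P"].selected
        assert "0.8" in best["P"].reason

    def test_argmax_among_survivors(self):
        x = np.linspace(1, 5, 30)
        y = 2 * x + RNG.normal(0, 0.05, 30)
        noisy = x + RNG.normal(0, 0.35, 30)  # weaker but above threshold
        best = select_best_models(self._props(y), {"clean": x, "noisy": noisy}, 1)
        assert best["P"].results.regression_model.index_name == "clean"

    def test_degenerate_constant_property_flagged(self):
        x = np.linspace(1, 5, 10)
        best = select_best_models(self._props(np.full(10, 7.0)), {"TI": x}, 1)
        assert not best["P"].selected and "degenerate" in best["P"].reason

    def test_benzenoid_bp_best_is_packaged_descriptor(self, benzenoid_ti, benzenoid_properties):
        best = select_best_models(
            benzenoid_properties[["BP"]], {"RRR_-1": benzenoid_ti.to_numpy()}, 1)
        assert best["BP"].results.regression_model.index_name == "RRR_-1"
        assert round(best["BP"].results.rsquared, 4) == 0.9587


class TestComparisonReport:
    def test_row_per_property_with_both_r2(self):
        x = np.linspace(1, 5, 26)
        props = pd.DataFrame({"A": 3 * x + RNG.normal(0, 0.05, 26),
                              "B": x**2 + RNG.normal(0, 0.05, 26)})
        report = comparison_report(props, {"RRX": x}, {"X": x + RNG.normal(0, 0.2, 26)})
        assert len(report) == 2
        assert {"classical_r2", "rr_linear_r2", "rr_quadratic_r2"} <= set(report.columns)
        assert report["rr_quadratic_r2"].ge(report["rr_linear_r2"] - 1e-12).all()

    def test_packaged_inputs_give_twelve_rows(self, benzenoid_ti, benzenoid_properties):
        x = benzenoid_ti.to_numpy()
        report = comparison_report(benzenoid_properties, {"RRR_-1": x}, {"proxy": x})
        assert len(report) == 12


def test_plot_fit_writes_figure(tmp_path, benzenoid_ti, benzenoid_properties):
    from rrqspr.plotting import plot_fit

    res = fit_polynomial(benzenoid_ti.to_numpy(), benzenoid_properties["BP"].to_numpy(),
                         2, "BP", "RRR_-1")
    out = tmp_path / "bp.png"
    plot_fit(res, str(out))
    assert out.stat().st_size > 0
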