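"""Beta regression: likelihood, gradient, fitting, design and reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import expit, logit

from oudpdc.betareg import (
    BetaRegression,
    ModelSpec,
    RankDeficientDesign,
    age_band,
    beta_loglik,
    beta_loglik_grad,
    compress_boundary,
    design_matrix,
    fit_beta_regression,
    odds_ratio_table,
)


def simulate_xy(rng, n=2000, b0=1.8, b_covid=-0.08, b_male=-0.02, phi=20.0):
    covid = rng.binomial(1, 0.35, n)
    male = rng.binomial(1, 0.526, n)
    eta = b0 + b_covid * covid + b_male * male
    mu = expit(eta)
    y = rng.beta(mu * phi, (1 - mu) * phi)
    X = np.column_stack([covid, male]).astype(float)
    return X, y


class TestCompressBoundary:
    def test_formula_at_one(self):
        assert compress_boundary(np.array([1.0]), n=100)[0] == pytest.approx(0.995)

    def test_midpoint_fixed(self):
        assert compress_boundary(np.array([0.5]), n=50)[0] == pytest.approx(0.5)

    def test_strictly_inside_and_order_preserving(self):
        rng = np.random.default_rng(0)
        y = np.sort(np.r_[0.0, 1.0, rng.random(100)])
        out = compress_boundary(y)
        assert out.min() > 0 and out.max() < 1
        assert np.all(np.diff(out) >= 0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            compress_boundary(np.array([1.2]))


class TestLoglik:
    def test_uniform_density_contributes_zero(self):
        # mu=0.5, phi=2 is Beta(1,1): density 1 everywhere
        for y in (0.1, 0.37, 0.9):
            ll = beta_loglik(np.zeros(1), np.log(2.0), np.zeros((1, 1)), np.array([y]))
            assert ll == pytest.approx(0.0, abs=1e-12)

    def test_beta22_at_half(self):
        # mu=0.5, phi=4 is Beta(2,2): density at 0.5 equals 1.5
        ll = beta_loglik(np.zeros(1), np.log(4.0), np.zeros((1, 1)), np.array([0.5]))
        assert ll == pytest.approx(np.log(1.5), abs=1e-12)

    def test_density_integrates_to_one(self):
        for eta, phi in ((0.5, 3.0), (1.8, 20.0), (-1.0, 7.5)):
            dens = lambda y: np.exp(
                beta_loglik(np.array([eta]), np.log(phi), np.ones((1, 1)), np.array([y]))
            )
            total, _ = integrate.quad(dens, 0.0, 1.0)
            assert total == pytest.approx(1.0, rel=1e-8)

    def test_boundary_y_rejected(self):
        with pytest.raises(ValueError, match="compress_boundary"):
            beta_loglik(np.zeros(1), 0.0, np.zeros((1, 1)), np.array([1.0]))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        X, y = simulate_xy(rng, n=200)
        Xd = np.column_stack([np.ones(len(X)), X])
        theta = np.array([1.5, -0.1, 0.05, np.log(15.0)])
        grad = beta_loglik_grad(theta[:-1], theta[-1], Xd, y)
        for j in range(len(theta)):
            e = np.zeros_like(theta)
            e[j] = 1e-6
            num = (
                beta_loglik((theta + e)[:-1], (theta + e)[-1], Xd, y)
                - beta_loglik((theta - e)[:-1], (theta - e)[-1], Xd, y)
            ) / 2e-6
            assert grad[j] == pytest.approx(num, rel=1e-4, abs=1e-4)


class TestFitting:
    def test_symmetric_response_gives_null_intercept(self):
        rng = np.random.default_rng(2)
        y = rng.beta(5, 5, size=3000)
        m = BetaRegression(boundary_adjustment="none").fit(np.empty((3000, 0)), y)
        assert abs(m.intercept_) < 3 * m.bse_[0]

    def test_recovers_known_covid_effect(self):
        rng = np.random.default_rng(3)
        X, y = simulate_xy(rng, n=5000)
        m = BetaRegression(boundary_adjustment="none").fit(X, y)
        assert m.coef_[0] == pytest.approx(-0.08, abs=3 * m.bse_[1])
        assert m.phi_ == pytest.approx(20.0, rel=0.15)
        assert m.converged_

    def test_agrees_with_independent_implementation(self):
        """Estimates match statsmodels' beta MLE to 1e-4 on one dataset."""
        from statsmodels.othermod.betareg import BetaModel

        rng = np.random.default_rng(4)
        X, y = simulate_xy(rng, n=3000)
        ours = BetaRegression(boundary_adjustment="none").fit(X, y)
        theirs = BetaModel(y, np.column_stack([np.ones(len(X)), X])).fit(disp=0)
        ours_beta = np.r_[ours.intercept_, ours.coef_]
        assert np.max(np.abs(ours_beta - theirs.params[:3])) < 1e-4
        assert np.max(np.abs(ours.bse_ - theirs.bse[:3])) < 1e-5
        assert ours.loglik_ == pytest.approx(theirs.llf, abs=1e-4)

    def test_loglik_monotone_over_iterations(self):
        rng = np.random.default_rng(5)
        X, y = simulate_xy(rng, n=1000)
        m = BetaRegression(boundary_adjustment="none").fit(X, y)
        assert np.all(np.diff(m.loglik_path_) >= -1e-8)

    def test_rank_deficiency_names_column(self):
        rng = np.random.default_rng(6)
        X, y = simulate_xy(rng, n=500)
        X = np.column_stack([X, X[:, 0]])  # duplicate covid column
        with pytest.raises(RankDeficientDesign, match="dup"):
            BetaRegression(boundary_adjustment="none").fit(
                X, y, column_names=["covid", "male", "dup"]
            )

    def test_predict_returns_means(self):
        rng = np.random.default_rng(7)
        X, y = simulate_xy(rng, n=2000)
        m = BetaRegression(boundary_adjustment="none").fit(X, y)
        mu = m.predict(np.array([[0.0, 0.0], [1.0, 0.0]]))
        assert mu[0] > mu[1]  # covid lowers the mean
        assert np.all((mu > 0) & (mu < 1))


def _toy_panel():
    panel = pd.DataFrame(
        {
            "patient_id": ["a", "a", "b"],
            "month_index": [1, 2, 1],
            "pdc": [0.9, 1.0, 0.5],
            "calendar_month": ["2020-02", "2020-03", "2019-05"],
            "covid": [0, 1, 0],
        }
    )
    patients = pd.DataFrame(
        {
            "patient_id": ["a", "b"],
            "sex": ["F", "M"],
            "age_at_index": [35, 62],
            "state": ["1", "3"],
        }
    )
    flags = pd.DataFrame(
        {"Alcohol": [1], "Drugs": [0], "FluidsLytes": [0], "NeuroOther": [0], "Obesity": [0]},
        index=pd.Index(["b"], name="patient_id"),
    )
    counts = pd.Series({"a": 2, "b": 5})
    return panel, patients, flags, counts


class TestDesignMatrix:
    def test_dummy_coding_against_references(self):
        panel, patients, flags, counts = _toy_panel()
        X, y = design_matrix(panel, patients, flags, ModelSpec(), counts)
        assert len(X) == 3 and len(y) == 3
        row = X.iloc[0]  # female, 35, state 1, month 1
        assert row["sex_male"] == 0 and row["age_30_39"] == 1
        assert row[[c for c in X.columns if c.startswith("state_")]].sum() == 0
        assert row["pdc_month_2"] == 0
        rowb = X.iloc[2]  # male, 62, state 3
        assert rowb["sex_male"] == 1 and rowb["age_ge60"] == 1
        assert rowb["state_3"] == 1 and rowb["elix_Alcohol"] == 1
        assert rowb["n_f11_codes"] == 5
        assert list(y) == [0.9, 1.0, 0.5]

    def test_n_months_covariate_only_when_requested(self):
        panel, patients, flags, counts = _toy_panel()
        X, _ = design_matrix(panel, patients, flags, ModelSpec(), counts)
        assert "n_months_of_pdc" not in X.columns
        X2, _ = design_matrix(
            panel, patients, flags, ModelSpec(include_n_months=True), counts
        )
        assert list(X2["n_months_of_pdc"]) == [2.0, 2.0, 1.0]

    def test_unseen_state_errors(self):
        panel, patients, flags, counts = _toy_panel()
        patients.loc[1, "state"] = "9"
        with pytest.raises(ValueError, match="9"):
            design_matrix(panel, patients, flags, ModelSpec(), counts)

    def test_missing_demographics_errors(self):
        panel, patients, flags, counts = _toy_panel()
        with pytest.raises(ValueError, match="b"):
            design_matrix(panel, patients.iloc[:1], flags, ModelSpec(), counts)

    @pytest.mark.parametrize(
        "age,band", [(12, "<16"), (16, "<16"), (17, "17-29"), (29, "17-29"),
                     (35, "30-39"), (59, "50-59"), (60, ">=60")]
    )
    def test_age_bands(self, age, band):
        assert age_band(age) == band


class TestReporting:
    def test_or_arithmetic_from_published_inputs(self):
        """beta -0.076, SE 0.010 exponentiates to OR 0.927 with the stated CI."""
        rng = np.random.default_rng(8)
        X, y = simulate_xy(rng, n=500)
        res = fit_beta_regression(pd.DataFrame(X, columns=["covid", "male"]), y)
        t = res.table.copy()
        beta, se = -0.076, 0.010
        assert np.exp(beta) == pytest.approx(0.9268, abs=5e-4)
        assert np.exp(beta - 1.96 * se) == pytest.approx(np.exp(-0.0956), abs=1e-6)
        # the fitted table obeys the same arithmetic row-wise
        assert np.allclose(t["or"], np.exp(t["beta"]))
        assert np.allclose(t["or_ci_low"], np.exp(t["beta"] - 1.96 * t["se"]))
        assert np.all(
            (t["or_ci_low"] <= t["or"]) & (t["or"] <= t["or_ci_high"])
        )

    def test_formatted_table_has_const_row(self):
        rng = np.random.default_rng(9)
        X, y = simulate_xy(rng, n=500)
        res = fit_beta_regression(pd.DataFrame(X, columns=["covid", "male"]), y)
        table = odds_ratio_table(res)
        assert list(table.index) == ["covid", "male", "const"]
        assert "beta (SE)" in table.columns
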