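"""Logistic model: closed-form oracles, score equations, stepwise behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from alrisk.errors import FitError
from alrisk.logistic import (
    ModelSpec,
    backward_stepwise,
    design_matrix,
    fit_logistic,
    multivariate_table,
    predict_risk,
    terms_for,
)
from alrisk.simulate import generate_cohort
from tests.conftest import expand_counts


@pytest.fixture(scope="module")
def sex_fit(sex_counts_cohort):
    spec = ModelSpec(terms=tuple(terms_for(["sex"])))
    return fit_logistic(sex_counts_cohort, spec), sex_counts_cohort


def test_intercept_only_closed_form(sex_counts_cohort):
    """65 leaks of 736: intercept-only MLE is ln(65/671)."""
    fit = fit_logistic(sex_counts_cohort, ModelSpec(terms=()))
    assert fit.intercept == pytest.approx(math.log(65 / 671), abs=1e-8)


def test_sex_only_coefficient_is_2x2_log_odds_ratio(sex_fit):
    """Closed-form 2x2 oracle: beta_female = ln(12*411 / (260*53))."""
    fit, _ = sex_fit
    expected = math.log((12 * 411) / (260 * 53))
    assert fit.coefficients["female"] == pytest.approx(expected, abs=1e-8)


def test_score_equations_at_convergence(sex_fit):
    fit, cohort = sex_fit
    p = predict_risk(fit, cohort.df)
    resid = cohort.leak - p
    assert abs(resid.sum()) < 1e-6
    X = design_matrix(cohort.df, fit.spec)
    for col in X.columns:
        assert abs((X[col].to_numpy() * resid).sum()) < 1e-6


def test_agreement_with_generic_optimizer(study_config):
    """30-record toy fit vs direct likelihood maximisation by scipy BFGS."""
    cohort = generate_cohort(study_config, seed=11)
    df = cohort.df.head(30).copy()
    df["leak"] = (np.random.default_rng(5).random(30) < 0.4).astype(int)
    spec = ModelSpec(terms=tuple(terms_for(["sex", "op_time_min"])))
    fit = fit_logistic(df, spec)

    X = np.column_stack([np.ones(30), design_matrix(df, spec).to_numpy(float)])
    y = df["leak"].to_numpy(float)

    def nll(beta):
        lp = X @ beta
        return -(y * lp - np.logaddexp(0.0, lp)).sum()

    res = minimize(nll, np.zeros(X.shape[1]), method="BFGS", tol=1e-12)
    ours = np.concatenate([[fit.intercept], fit.coefficients.to_numpy()])
    assert np.allclose(ours, res.x, atol=1e-6)


def test_odds_ratios_are_exp_coefficients(sex_fit):
    fit, _ = sex_fit
    assert np.allclose(fit.odds_ratios["OR"], np.exp(fit.coefficients), rtol=1e-12)
    assert (fit.odds_ratios["ci_low"] <= fit.odds_ratios["OR"]).all()
    assert (fit.odds_ratios["OR"] <= fit.odds_ratios["ci_high"]).all()


class TestPredictRisk:
    def test_reference_record_is_sigmoid_intercept(self, sex_fit):
        fit, _ = sex_fit
        rec = {"sex": "M", "leak": 0}
        assert predict_risk(fit, rec) == pytest.approx(expit(fit.intercept), abs=1e-12)

    def test_prediction_odds_ratio_equals_fitted_or(self, study_cohort):
        spec = ModelSpec(terms=tuple(terms_for(["sex", "transfusion"])))
        fit = fit_logistic(study_cohort, spec)
        base = dict(study_cohort.df.iloc[0])
        p0 = predict_risk(fit, {**base, "transfusion": 0})
        p1 = predict_risk(fit, {**base, "transfusion": 1})
        got = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert got == pytest.approx(float(fit.odds_ratios.loc["transfusion", "OR"]), rel=1e-9)

    def test_hand_computed_linear_predictor(self, study_cohort):
        spec = ModelSpec(terms=tuple(terms_for(["sex", "location", "op_time_min"])))
        fit = fit_logistic(study_cohort, spec)
        rec = {"sex": "F", "location": "low", "op_time_min": 250.0}
        lp = (
            fit.intercept
            + fit.coefficients["female"]
            + fit.coefficients["location[low]"]
            + fit.coefficients["op_time_h"] * 250.0 / 60.0
        )
        assert predict_risk(fit, rec) == pytest.approx(expit(lp), abs=1e-12)


class TestBackwardStepwise:
    def test_noise_term_removed_strong_term_kept(self, study_cohort):
        fit = backward_stepwise(study_cohort, ["sex", "bmi"], stay_alpha=0.05)
        names = [t.name for t in fit.spec.terms]
        assert "female" in names
        assert "bmi5" not in names

    def test_no_removal_fixed_point(self, study_cohort):
        full = fit_logistic(study_cohort, ModelSpec(terms=tuple(terms_for(["sex", "transfusion"]))))
        stepped = backward_stepwise(study_cohort, ["sex", "transfusion"], stay_alpha=0.05)
        assert [t.name for t in stepped.spec.terms] == [t.name for t in full.spec.terms]
        assert np.allclose(stepped.coefficients, full.coefficients)

    def test_stay_alpha_one_keeps_full_model(self, study_cohort):
        fit = backward_stepwise(study_cohort, ["sex", "age_years", "bmi"], stay_alpha=1.0)
        assert {t.name for t in fit.spec.terms} == {"female", "age_dec", "bmi5"}

    def test_empty_candidates_intercept_only_with_warning(self, study_cohort):
        fit = backward_stepwise(study_cohort, [])
        assert fit.spec.terms == ()
        assert any("intercept-only" in n for n in fit.notes)

    def test_categorical_terms_removed_as_blocks(self, study_cohort):
        """Location enters/leaves with both dummies; never a lone level."""
        fit = backward_stepwise(study_cohort, ["location", "bmi"], stay_alpha=0.05)
        cols = list(fit.coefficients.index)
        assert ("location[mid]" in cols) == ("location[low]" in cols)


class TestFitErrors:
    def test_constant_term_raises(self, study_cohort):
        df = study_cohort.df.copy()
        df["transfusion"] = 0
        with pytest.raises(FitError, match="constant"):
            fit_logistic(df, ModelSpec(terms=tuple(terms_for(["transfusion"]))))

    def test_singular_design_names_collinear_terms(self, study_cohort):
        dup = terms_for(["sex"])[0]
        dup2 = dup.__class__(**{**dup.__dict__, "name": "female_copy"})
        spec = ModelSpec(terms=(dup, dup2))
        with pytest.raises(FitError, match="female_copy|singular"):
            fit_logistic(study_cohort, spec)

    def test_perfect_separation_raises(self):
        cohort = expand_counts([({"transfusion": 1}, 20, 20), ({"transfusion": 0}, 0, 40)])
        with pytest.raises(FitError):
            fit_logistic(cohort, ModelSpec(terms=tuple(terms_for(["transfusion"]))))


def test_coefficient_recovery_improves_with_n(flat_config):
    """Bias of the female log-OR shrinks as the cohort grows."""
    import dataclasses

    truth = math.log(flat_config.effect_sizes["female"])
    spec = ModelSpec(terms=tuple(terms_for(["sex", "asa", "location", "op_time_min", "transfusion"])))
    bias = {}
    for n in (2000, 20000):
        cfg = dataclasses.replace(flat_config, n_patients=n)
        errs = [
            fit_logistic(generate_cohort(cfg, seed=s), spec).coefficients["female"] - truth
            for s in range(4)
        ]
        bias[n] = abs(np.mean(errs))
    assert bias[20000] < max(bias[2000], 0.05)


def test_multivariate_table_layout(study_cohort):
    fit = backward_stepwise(study_cohort, ["sex", "location", "transfusion"], stay_alpha=1.0)
    table = multivariate_table(fit)
    assert list(table.columns) == ["term", "level", "OR", "ci_low", "ci_high", "p"]
    assert len(table) == len(fit.coefficients)
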