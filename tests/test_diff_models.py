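"""OLS models, the combined estimator, and the evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrebs.diff_models import (
    assemble_records,
    combine_estimates,
    correlation_matrix,
    evaluate_fit,
    fit_model,
    fit_ols,
    predict,
)


def normal_equations(y, X):
    """Independent closed-form OLS oracle: solve (X'X) b = X'y."""
    design = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(design.T @ design, design.T @ y)


def series(values, start=0):
    idx = pd.MultiIndex.from_tuples(
        [("chr1", start + i) for i in range(len(values))], names=["chrom", "pos"]
    )
    return pd.Series(values, index=idx, dtype=float)


def make_records(y=None, r=None, x1=None, x2=None):
    return assemble_records(
        y=None if y is None else series(y),
        r=None if r is None else series(r),
        x1=None if x1 is None else series(x1),
        x2=None if x2 is None else series(x2),
    )


class TestFitOls:
    def test_perfect_linear_fit(self):
        x = np.arange(10.0)
        params, fitted, r2 = fit_ols(2 + 3 * x, x)
        assert params == pytest.approx([2.0, 3.0])
        assert r2 == pytest.approx(1.0)
        assert fitted == pytest.approx(2 + 3 * x)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="zero response variance"):
            fit_ols(np.full(10, 7.0), np.arange(10.0))

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant predictor"):
            fit_ols(np.arange(10.0), np.full(10, 1.0))

    def test_rank_deficient_design_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            fit_ols(x + 1, np.column_stack([x, 2 * x]))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            fit_ols(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0]))

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(12)
        for k in (1, 2):
            for _ in range(20):
                X = rng.normal(size=(50, k))
                y = rng.normal(size=50)
                params, _, _ = fit_ols(y, X)
                assert params == pytest.approx(normal_equations(y, X), abs=1e-8)

    def test_r_squared_equals_squared_obs_fitted_correlation(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            X = rng.normal(size=(80, 2))
            y = X @ [1.5, -0.7] + rng.normal(size=80)
            _, fitted, r2 = fit_ols(y, X)
            assert r2 == pytest.approx(np.corrcoef(y, fitted)[0, 1] ** 2, abs=1e-10)


class TestFitModel:
    def test_model1_identity_predictor(self):
        y = np.linspace(-50, 50, 30)
        fit = fit_model(make_records(y=y, r=y), 1)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.coefficients["r"] == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_model4_negative_rescaling_gives_negative_slope(self):
        # counts anti-correlate with methylation: x2 = -y/4 exactly
        y = np.linspace(-40, 40, 25)
        fit = fit_model(make_records(y=y, x2=-y / 4), 4)
        assert fit.coefficients["x2"] == pytest.approx(-4.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_model2_recovers_known_coefficients(self):
        rng = np.random.default_rng(99)
        n = 1000
        x1 = rng.normal(0, 20, n)
        x2 = rng.normal(0, 10, n)
        noise = rng.normal(0, 5, n)
        y = 1 + 0.8 * x1 - 0.5 * x2 + noise
        fit = fit_model(make_records(y=y, x1=x1, x2=x2), 2)
        # standard errors from the closed-form covariance of the oracle
        design = np.column_stack([np.ones(n), x1, x2])
        resid = y - design @ normal_equations(y, np.column_stack([x1, x2]))
        sigma2 = resid @ resid / (n - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(design.T @ design)))
        est = [fit.intercept, fit.coefficients["x1"], fit.coefficients["x2"]]
        for b, truth, s in zip(est, [1.0, 0.8, -0.5], se):
            assert abs(b - truth) < 3 * s

    def test_fit_uses_only_complete_rows(self):
        y = np.linspace(0, 29, 30)
        x1 = y.copy()
        x1[:10] = np.nan
        fit = fit_model(make_records(y=y, x1=x1), 3)
        assert fit.n == 20

    def test_slopes_invariant_under_sample_swap(self):
        rng = np.random.default_rng(17)
        y = rng.normal(0, 30, 200)
        x1 = 0.6 * y + rng.normal(0, 10, 200)
        x2 = -0.2 * y + rng.normal(0, 5, 200)
        fit = fit_model(make_records(y=y, x1=x1, x2=x2), 2)
        flipped = fit_model(make_records(y=-y, x1=-x1, x2=-x2), 2)
        assert flipped.coefficients["x1"] == pytest.approx(fit.coefficients["x1"])
        assert flipped.coefficients["x2"] == pytest.approx(fit.coefficients["x2"])
        assert flipped.intercept == pytest.approx(-fit.intercept)


class TestPredictAndCombine:
    def test_identity_prediction(self):
        y = np.linspace(-50, 50, 30)
        fit = fit_model(make_records(y=y, x1=y), 3)
        pred = predict(fit, make_records(y=[np.nan], x1=[37.0]))
        assert pred.iloc[0] == pytest.approx(37.0)

    def test_missing_predictor_yields_no_prediction(self):
        y = np.linspace(-50, 50, 30)
        fit = fit_model(make_records(y=y, x1=y), 3)
        x1 = np.array([1.0, np.nan, 3.0])
        pred = predict(fit, make_records(y=[0, 0, 0], x1=x1))
        assert len(pred) == 2

    def test_training_predictions_preserve_mean(self):
        rng = np.random.default_rng(31)
        y = rng.normal(10, 20, 100)
        x1 = 0.5 * y + rng.normal(0, 8, 100)
        records = make_records(y=y, x1=x1)
        fit = fit_model(records, 3)
        pred = predict(fit, records)
        assert pred.mean() == pytest.approx(y.mean())

    def test_combined_prefers_model2_where_available(self):
        m4 = series([1.0, 2.0, 3.0], start=0)
        m2 = series([10.0], start=1)  # only the middle dimer
        combined = combine_estimates(m4, m2)
        assert combined.tolist() == [1.0, 10.0, 3.0]

    def test_combined_support_is_union(self):
        m4 = series([1.0, 2.0], start=0)
        m2 = series([9.0, 8.0], start=1)
        combined = combine_estimates(m4, m2)
        assert set(combined.index) == set(m4.index) | set(m2.index)


class TestEvaluateFit:
    def test_worked_example(self):
        rep = evaluate_fit(series([0.0, 30.0, -50.0]), series([10.0, 20.0, -80.0]))
        assert rep.rmse == pytest.approx(19.1485, abs=1e-3)
        assert rep.mae == pytest.approx(16.6667, abs=1e-3)
        assert rep.methyl15 == pytest.approx(66.6667, abs=1e-3)
        assert rep.methyl25 == pytest.approx(66.6667, abs=1e-3)

    def test_perfect_fit(self):
        obs = series([0.0, 30.0, -50.0])
        rep = evaluate_fit(obs, obs.copy())
        assert rep.rmse == 0 and rep.mae == 0
        assert rep.methyl15 == 100.0 and rep.methyl25 == 100.0
        assert rep.correlation == pytest.approx(1.0)

    def test_constant_track_has_undefined_correlation(self):
        rep = evaluate_fit(series([1.0, 2.0, 3.0]), series([5.0, 5.0, 5.0]))
        assert rep.correlation is None

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="no dimers"):
            evaluate_fit(series([1.0]), series([1.0], start=10))

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=40),
           st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=250)
    def test_metric_inequalities(self, obs, seed):
        rng = np.random.default_rng(seed)
        fitted = rng.uniform(-100, 100, len(obs))
        rep = evaluate_fit(series(obs), series(fitted))
        assert rep.methyl25 >= rep.methyl15
        assert rep.rmse >= rep.mae >= 0
        d = np.abs(np.asarray(obs) - fitted)
        if not np.allclose(d, d[0]):
            assert rep.rmse > rep.mae


class TestCorrelationMatrix:
    def test_self_and_negation(self):
        t = series(np.arange(10.0))
        r, n = correlation_matrix({"a": t, "b": -t})
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert r.loc["b", "a"] == pytest.approx(-1.0)
        assert (n == 10).all().all()

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=10), rng.normal(size=10)
        r, _ = correlation_matrix({"a": series(a), "b": series(b)})
        expected = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert r.loc["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_insufficient_overlap_gives_nan(self):
        a = series([1.0, 2.0])
        b = series([1.0, 2.0], start=1)  # one common dimer
        r, n = correlation_matrix({"a": a, "b": b})
        assert np.isnan(r.loc["a", "b"])
        assert n.loc["a", "b"] == 1
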