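"""Fractional-polynomial transforms, logistic fitting, FP closed-test selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from prismor.cohort import CohortSpec, TrueOutcomeModel, assign_outcomes, generate_cohort
from prismor.model import (
    FractionalPolynomialLogisticRegression,
    fit_logistic,
    fp_terms,
    select_fp,
)


@pytest.mark.parametrize(
    "age, powers, expected",
    [
        (75.0, (2.0, 3.0), (0.5625, 0.421875)),
        (0.0, (2.0, 3.0), (0.0, 0.0)),
        (100.0, (2.0, 3.0), (1.0, 1.0)),
        (50.0, (-1.0,), (2.0,)),
        (100.0, (0.0,), (0.0,)),  # power 0 is the natural log
    ],
)
def test_fp_terms_arithmetic(age, powers, expected):
    assert fp_terms(age, powers) == pytest.approx(np.array([expected]))


def test_fp_repeated_power_adds_log_product():
    out = fp_terms(50.0, (2.0, 2.0))[0]
    x = 0.5
    assert out == pytest.approx((x**2, x**2 * np.log(x)))


def test_fp_log_power_rejects_zero_age():
    with pytest.raises(ValueError):
        fp_terms(0.0, (0.0,))
    with pytest.raises(ValueError):
        fp_terms(0.0, (-2.0,))


def test_null_data_recovers_intercept_only(rng):
    """With no true effects, slopes shrink to ~0 and the intercept to logit(prevalence)."""
    n = 20000
    design = pd.DataFrame(
        {"x1": rng.integers(0, 2, n).astype(float), "x2": rng.normal(size=n)}
    )
    y = rng.random(n) < 0.3
    fit = fit_logistic(design, y.astype(float), retention_alpha=1.01)
    assert fit.params["const"] == pytest.approx(logit(y.mean()), abs=0.05)
    assert abs(fit.params["x1"]) < 0.1 and abs(fit.params["x2"]) < 0.05


def test_duplicated_column_is_rank_deficient(rng):
    design = pd.DataFrame({"a": rng.normal(size=100)})
    design["b"] = design["a"]
    with pytest.raises(ValueError, match="rank"):
        fit_logistic(design, rng.integers(0, 2, 100).astype(float))


def test_complete_separation_raises(rng):
    x = np.concatenate([np.zeros(30), np.ones(30)])
    design = pd.DataFrame({"x": x})
    with pytest.raises(Exception, match="separat|failed"):
        fit_logistic(design, x.copy())


def test_backward_elimination_drops_noise_keeps_signal(rng):
    n = 6000
    signal = rng.integers(0, 2, n).astype(float)
    noise = rng.integers(0, 2, n).astype(float)
    y = (rng.random(n) < expit(-1.0 + 1.2 * signal)).astype(float)
    design = pd.DataFrame({"signal": signal, "noise": noise})
    fit = fit_logistic(design, y, retention_alpha=0.30)
    assert "signal" in fit.design_columns
    # refitting the retained design reproduces the selected fit exactly
    refit = fit_logistic(design[list(fit.design_columns)], y, retention_alpha=1.01)
    pd.testing.assert_series_equal(fit.params, refit.params)


def test_estimator_recovers_generating_coefficients():
    """Moderate-n sanity recovery; the strict tolerance check lives in acceptance."""
    spec = CohortSpec(n_patients=25000, seed=21)
    cohort = assign_outcomes(generate_cohort(spec), seed=22)
    est = FractionalPolynomialLogisticRegression(
        fp_powers=(2.0, 3.0), retention_alpha=1.01
    )
    est.fit(cohort)
    truth = TrueOutcomeModel()
    for term, beta in truth.coefficients.items():
        if term.startswith("age_fp"):
            continue
        assert est.coef_[term] == pytest.approx(beta, abs=max(0.12, 0.15 * abs(beta))), term


def test_estimator_is_sklearn_cloneable(cohort_1408):
    from sklearn.base import clone

    est = FractionalPolynomialLogisticRegression(fp_powers=(2.0, 3.0))
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
    est.fit(cohort_1408)
    p = est.predict_proba(cohort_1408)
    assert p.shape == (len(cohort_1408), 2)
    assert np.all((p > 0) & (p < 1))
    assert np.allclose(p.sum(axis=1), 1.0)


def test_model_document_round_trip(cohort_1408, tmp_path):
    import json

    est = FractionalPolynomialLogisticRegression(fp_powers=(2.0, 3.0)).fit(cohort_1408)
    path = tmp_path / "model.json"
    est.save(path)
    doc = json.loads(path.read_text())
    assert doc["fp_powers"] == [2.0, 3.0]
    assert doc["intercept"] == pytest.approx(est.intercept_)
    assert {t["name"] for t in doc["terms"]} == set(est.columns_)


# --- fractional-polynomial closed test --------------------------------------


def age_only_outcome(n, seed, b_lin=None, b_fp=None):
    rng = np.random.default_rng(seed)
    age = pd.Series(rng.uniform(20, 100, n))
    a = age / 100.0
    if b_lin is not None:
        lp = -1.5 + b_lin * a
    else:
        lp = -1.5 + b_fp[0] * a**2 + b_fp[1] * a**3
    y = (rng.random(n) < expit(lp)).astype(float)
    return age, y


def test_linear_truth_stops_at_linear():
    age, y = age_only_outcome(20000, seed=31, b_lin=1.8)
    powers = select_fp(pd.DataFrame(index=age.index), age, y)
    assert powers == (1.0,)


def test_no_effect_returns_none():
    age, y = age_only_outcome(400, seed=33, b_lin=0.0)
    assert select_fp(pd.DataFrame(index=age.index), age, y) is None


def test_fp2_truth_recovered_or_curve_matched():
    """Strong curvature: chosen FP2 pair equals (2,3) or matches its curve."""
    age, y = age_only_outcome(40000, seed=35, b_fp=(14.0, -12.5))
    powers = select_fp(pd.DataFrame(index=age.index), age, y)
    assert powers is not None and len(powers) == 2
    grid = np.linspace(20, 100, 81)
    truth_lp = 14.0 * (grid / 100) ** 2 - 12.5 * (grid / 100) ** 3
    design = pd.DataFrame(fp_terms(age.to_numpy(), powers), index=age.index)
    design.columns = [f"t{i}" for i in range(design.shape[1])]
    fit = fit_logistic(design, y, retention_alpha=1.01)
    curve = fp_terms(grid, powers) @ fit.params.drop("const").to_numpy()
    # curves compared after centering (intercepts differ by construction)
    diff = (curve - curve.mean()) - (truth_lp - truth_lp.mean())
    assert np.max(np.abs(diff)) < 0.15


def test_chosen_fp2_deviance_not_worse_than_linear():
    age, y = age_only_outcome(5000, seed=37, b_fp=(14.0, -12.5))
    lin = fit_logistic(
        pd.DataFrame({"a": age / 100}), y, retention_alpha=1.01
    )
    powers = select_fp(pd.DataFrame(index=age.index), age, y)
    design = pd.DataFrame(fp_terms(age.to_numpy(), powers or (1.0,)), index=age.index)
    design.columns = [f"t{i}" for i in range(design.shape[1])]
    best = fit_logistic(design, y, retention_alpha=1.01)
    assert best.deviance <= lin.deviance + 1e-8
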