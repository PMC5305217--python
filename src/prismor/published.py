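"""The published PRISMOR risk model, frozen as a reference scorer.

PRISMOR predicts the probability that an adult inpatient experiences at
least one clinically significant medication error (NCC MERP category D or
above) during the hospital stay.  The model is a logistic regression with a
second-degree fractional-polynomial age effect, ``(age/100)^2`` and
``(age/100)^3``, plus ten admission-time covariates.  The published slope
coefficients are the *corrected* log-odds ratios, i.e. the maximum-likelihood
estimates multiplied by a uniform shrinkage factor of 0.926 obtained from
bootstrap internal validation.

The predicted probability is

    p = 1 / (1 + exp(-(b0 + sum_i w_i * beta_i)))

with the corrected coefficients below.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

#: Uniform shrinkage factor applied to every slope of the published model.
PUBLISHED_SHRINKAGE: float = 0.926

#: Corrected (shrunken) log-odds ratios of the published model.
#: Age enters through (age/100)**2 and (age/100)**3; every other predictor
#: is a 0/1 flag except ``n_drugs`` (count of prescribed drugs).
PUBLISHED_COEFFICIENTS: dict[str, float] = {
    "age_fp2": 7.07,   # (age/100)**2
    "age_fp3": -6.26,  # (age/100)**3
    "n_drugs": 0.14,
    "treatment_before_admission": 1.60,
    "bpmh_available": -0.64,
    "atc_N05": 0.31,
    "atc_B05": -0.16,
    "surgical_admission": 0.29,
    "prior_hosp_30d": -0.36,
    "admission_from_ed": 0.27,
    "night_admission": -0.18,
    "admission_from_outside": -0.51,
}

PUBLISHED_INTERCEPT: float = -3.83

#: Cohort columns the scorer needs (age plus the ten binary/count predictors).
REQUIRED_FIELDS: tuple[str, ...] = ("age",) + tuple(
    k for k in PUBLISHED_COEFFICIENTS if not k.startswith("age_fp")
)


def linear_predictor(patients: pd.DataFrame) -> np.ndarray:
    """Corrected linear predictor of the published model, one value per row.

    Raises ``KeyError`` naming the first missing predictor column; no
    imputation is attempted.
    """
    for field in REQUIRED_FIELDS:
        if field not in patients.columns:
            raise KeyError(f"missing predictor column: {field!r}")
        if patients[field].isna().any():
            raise ValueError(f"predictor column {field!r} contains missing values")
    a = np.asarray(patients["age"], dtype=float) / 100.0
    lp = PUBLISHED_INTERCEPT + PUBLISHED_COEFFICIENTS["age_fp2"] * a**2
    lp = lp + PUBLISHED_COEFFICIENTS["age_fp3"] * a**3
    for name, beta in PUBLISHED_COEFFICIENTS.items():
        if name.startswith("age_fp"):
            continue
        lp = lp + beta * np.asarray(patients[name], dtype=float)
    return lp


def predict_probability(patients: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
    """Predicted probability of a clinically significant medication error.

    Accepts a cohort table or a single patient given as a mapping; returns
    an array of probabilities strictly inside (0, 1).
    """
    if isinstance(patients, Mapping):
        patients = pd.DataFrame([patients])
    from scipy.special import expit

    return expit(linear_predictor(patients))


def unshrink_odds_ratio(corrected_logor: float, shrinkage: float = PUBLISHED_SHRINKAGE) -> float:
    """Reconstruct the uncorrected odds ratio from a corrected log-odds ratio.

    The published table stores shrunken log-odds ratios next to the
    *unshrunken* odds-ratio column, so the OR column is recovered as
    ``exp(corrected / shrinkage)``.
    """
    if shrinkage <= 0:
        raise ValueError("shrinkage factor must be positive")
    return math.exp(corrected_logor / shrinkage)


class PublishedPrismorModel:
    """Frozen scorer exposing the published coefficients.

    Mimics the fitted-estimator surface (``predict_proba``,
    ``decision_function``) so it can stand in wherever a freshly fitted
    model is accepted, e.g. as the ranking key of a triage strategy.
    """

    intercept_: float = PUBLISHED_INTERCEPT
    shrinkage_: float = PUBLISHED_SHRINKAGE

    def __init__(self) -> None:
        self.coef_ = dict(PUBLISHED_COEFFICIENTS)

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return linear_predictor(X)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = predict_probability(X)
        return np.column_stack([1.0 - p, p])

    def uncorrected_odds_ratios(self) -> dict[str, float]:
        """Per-term odds ratios with the shrinkage divided back out."""
        return {k: unshrink_odds_ratio(v) for k, v in self.coef_.items()}


def age_risk_profile(
    grid: np.ndarray | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Peak of the n-shaped age effect and the odds-ratio curve over age.

    The age effect is ``b2*(a)^2 + b3*(a)^3`` with ``a = age/100``; its
    interior maximum is at ``a* = 2*b2 / (3*|b3|)``.  The peak age uses the
    corrected coefficients (scale-free ratio, so correction cancels), while
    the peak odds ratio relative to the age-zero reference is evaluated with
    the unshrunken coefficients, matching how the published odds-ratio
    column is reported.

    Returns ``(peak_age_years, peak_odds_ratio, curve)`` where ``curve`` has
    columns ``age`` and ``odds_ratio``.
    """
    b2 = PUBLISHED_COEFFICIENTS["age_fp2"]
    b3 = PUBLISHED_COEFFICIENTS["age_fp3"]
    a_star = 2.0 * b2 / (3.0 * abs(b3))
    peak_age = a_star * 100.0
    b2u = b2 / PUBLISHED_SHRINKAGE
    b3u = b3 / PUBLISHED_SHRINKAGE
    peak_or = math.exp(b2u * a_star**2 + b3u * a_star**3)
    if grid is None:
        grid = np.arange(18, 101, dtype=float)
    a = np.asarray(grid, dtype=float) / 100.0
    curve = pd.DataFrame(
        {"age": grid, "odds_ratio": np.exp(b2u * a**2 + b3u * a**3)}
    )
    return peak_age, peak_or, curve
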