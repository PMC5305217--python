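"""Internal validation: discrimination, calibration, bootstrap optimism.

Apparent performance of a risk model evaluated on its own development data
is optimistic.  Following the standard bootstrap recipe, the whole model
building procedure is repeated on each bootstrap resample; the difference
between a replicate model's performance on its own resample and on the
original data estimates the optimism, and apparent minus mean optimism
gives the corrected estimate.  The corrected calibration slope doubles as
the uniform shrinkage factor applied to the final coefficients.

Discrimination is the c-statistic (probability a random event patient is
ranked above a random non-event patient, ties counted one half).
Calibration is summarized by the slope of a logistic recalibration of the
outcome on the model's linear predictor and, with the slope fixed at one,
the calibration-in-the-large intercept.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from sklearn.base import clone
from sklearn.metrics import roc_auc_score


def c_statistic(probabilities: np.ndarray, outcomes: np.ndarray) -> float:
    """Concordance probability for a binary outcome; ties count 1/2."""
    y = np.asarray(outcomes)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("c-statistic undefined: only one outcome class present")
    return float(roc_auc_score(y, p))


def _linear_predictor(probabilities: np.ndarray) -> np.ndarray:
    p = np.asarray(probabilities, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    lp = logit(p)
    if np.ptp(lp) < 1e-12:
        raise ValueError("constant linear predictor; calibration undefined")
    return lp


def calibration_fit(probabilities: np.ndarray, outcomes: np.ndarray) -> tuple[float, float]:
    """(calibration-in-the-large intercept, calibration slope).

    The slope is the coefficient of a logistic regression of outcomes on
    the linear predictor; the intercept is re-estimated with the slope
    fixed at one (offset logistic), so a well-calibrated model gives
    (0, 1) and an overfitted one a slope below 1.
    """
    lp = _linear_predictor(probabilities)
    y = np.asarray(outcomes, dtype=float)
    slope_fit = sm.Logit(y, sm.add_constant(lp)).fit(disp=0, maxiter=200)
    slope = float(slope_fit.params[1])
    citl_fit = sm.GLM(
        y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=lp
    ).fit()
    citl = float(citl_fit.params[0])
    return citl, slope


@dataclass
class ValidationReport:
    """Apparent and optimism-corrected performance of one model pipeline."""

    apparent_c: float
    corrected_c: float
    apparent_citl: float
    corrected_citl: float
    apparent_slope: float
    corrected_slope: float
    shrinkage_factor: float
    n_bootstrap: int
    n_failed: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def bootstrap_validate(
    estimator,
    X: pd.DataFrame,
    y: np.ndarray | None = None,
    b: int = 500,
    seed: int = 0,
    resampler=None,
    max_failure_fraction: float = 0.20,
) -> ValidationReport:
    """Harrell bootstrap optimism correction of c-statistic and calibration.

    ``estimator`` is an unfitted model-building recipe (cloned and refitted
    from scratch, including any internal selection, on every resample).
    ``resampler(rng, n) -> indices`` can override the resampling for tests.
    Replicates whose refit fails are dropped; more than
    ``max_failure_fraction`` failures aborts.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if y is None:
        y = X["outcome"]
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)

    apparent_model = clone(estimator).fit(X, y)
    p_app = apparent_model.predict_proba(X)[:, 1]
    apparent_c = c_statistic(p_app, y)
    apparent_citl, apparent_slope = calibration_fit(p_app, y)

    opt_c, opt_citl, opt_slope = [], [], []
    n = len(X)
    failed = 0
    for _ in range(b):
        idx = rng.integers(0, n, size=n) if resampler is None else resampler(rng, n)
        Xb, yb = X.iloc[idx].reset_index(drop=True), y[idx]
        try:
            mb = clone(estimator).fit(Xb, yb)
            p_boot = mb.predict_proba(Xb)[:, 1]
            p_orig = mb.predict_proba(X)[:, 1]
            cb, co = c_statistic(p_boot, yb), c_statistic(p_orig, y)
            citl_b, slope_b = calibration_fit(p_boot, yb)
            citl_o, slope_o = calibration_fit(p_orig, y)
        except Exception:
            failed += 1
            if failed > max_failure_fraction * b:
                raise RuntimeError(
                    f"{failed}/{b} bootstrap replicates failed to refit"
                )
            continue
        opt_c.append(cb - co)
        opt_citl.append(citl_b - citl_o)
        opt_slope.append(slope_b - slope_o)

    corrected_slope = apparent_slope - float(np.mean(opt_slope))
    return ValidationReport(
        apparent_c=apparent_c,
        corrected_c=apparent_c - float(np.mean(opt_c)),
        apparent_citl=apparent_citl,
        corrected_citl=apparent_citl - float(np.mean(opt_citl)),
        apparent_slope=apparent_slope,
        corrected_slope=corrected_slope,
        shrinkage_factor=corrected_slope,
        n_bootstrap=b,
        n_failed=failed,
    )


def apply_shrinkage(model, factor: float, X: pd.DataFrame | None = None, y=None):
    """Uniformly shrink a fitted model's slopes and re-anchor its intercept.

    Every slope coefficient is multiplied by ``factor``; when fitting data
    are supplied the intercept is re-estimated by an intercept-only
    offset logistic fit on the shrunken linear predictor, which restores
    mean predicted probability = observed prevalence.
    """
    if factor <= 0:
        raise ValueError("shrinkage factor must be positive")
    shrunk = copy.deepcopy(model)
    shrunk.coef_ = model.coef_ * factor
    shrunk.shrinkage_ = factor
    if X is not None:
        if y is None:
            y = X["outcome"]
        y = np.asarray(y, dtype=float)
        offset = shrunk.decision_function(X) - shrunk.intercept_
        fit = sm.GLM(
            y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=offset
        ).fit()
        shrunk.intercept_ = float(fit.params[0])
    return shrunk


def calibration_curve(
    probabilities: np.ndarray,
    outcomes: np.ndarray,
    span: float = 0.75,
    n_deciles: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Smoothed observed-vs-predicted calibration curve plus a decile table.

    The curve is a local linear (lowess) regression of the binary outcome
    on the predicted probability with the given span; the table groups
    patients into risk deciles with mean predicted and observed rates.
    """
    _linear_predictor(probabilities)  # validates inputs
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    smoothed = sm.nonparametric.lowess(y, p, frac=span, return_sorted=True)
    curve = pd.DataFrame(smoothed, columns=["predicted", "observed"]).drop_duplicates(
        "predicted"
    )
    bins = pd.qcut(p, n_deciles, duplicates="drop")
    table = (
        pd.DataFrame({"bin": bins, "p": p, "y": y})
        .groupby("bin", observed=True)
        .agg(n=("y", "size"), mean_predicted=("p", "mean"), observed_rate=("y", "mean"))
        .reset_index(drop=True)
    )
    return curve, table
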