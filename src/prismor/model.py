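"""Multivariable logistic regression with fractional-polynomial age terms.

The development model is an ordinary maximum-likelihood logistic regression
over admission covariates, with the continuous age effect modelled by
second-degree fractional polynomials (FP2): age is divided by 100 and
raised to a pair of powers from {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (0 denotes
the natural log; a repeated power (p, p) contributes x^p and x^p*ln x).
The power pair is chosen by deviance with the usual closed test sequence
(any age effect? non-linear? FP2 over FP1?), and covariates are then pruned
by backward elimination on Wald p-values against a deliberately permissive
retention threshold (default p < 0.30) so weakly informative predictors are
kept for prediction.

The estimator follows the scikit-learn protocol (``fit`` /
``predict_proba`` / ``get_params``) but consumes a named-column DataFrame,
since the fractional-polynomial transform is tied to the age column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

#: The fractional-polynomial power set; 0 stands for the natural logarithm.
FP_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: Columns never used as predictors.
NON_PREDICTOR_COLUMNS: tuple[str, ...] = ("patient_id", "outcome")


def _fp_name(power: float, repeated: bool = False) -> str:
    tag = "log" if power == 0 else f"{power:g}"
    return f"age_fp({tag})xlog" if repeated else f"age_fp({tag})"


def fp_terms(
    age_years: np.ndarray | float,
    powers: tuple[float, ...],
    scale: float = 100.0,
) -> np.ndarray:
    """Fractional-polynomial transforms of age.

    Each power p maps age to ``(age/scale)**p``, with p = 0 meaning
    ``ln(age/scale)``; a repeated power (p, p) yields ``x**p`` and
    ``x**p * ln(x)``.  Returns an array of shape (n, len(powers)).
    """
    x = np.atleast_1d(np.asarray(age_years, dtype=float)) / scale
    if any(p <= 0 for p in powers) and np.any(x <= 0):
        raise ValueError("age must be positive for log or negative powers")
    cols = []
    prev: float | None = None
    for p in powers:
        base = np.log(x) if p == 0 else x**p
        if prev is not None and p == prev:
            base = (np.log(x) if p == 0 else x**p) * np.log(x)
        cols.append(base)
        prev = p
    return np.column_stack(cols)


def _fp_frame(age: pd.Series, powers: tuple[float, ...], scale: float) -> pd.DataFrame:
    values = fp_terms(np.asarray(age, dtype=float), powers, scale)
    names, prev = [], None
    for p in powers:
        names.append(_fp_name(p, repeated=prev is not None and p == prev))
        prev = p
    return pd.DataFrame(values, columns=names, index=age.index)


class SeparationError(RuntimeError):
    """Raised when the likelihood is unbounded (complete separation)."""


@dataclass
class LogisticFit:
    """Plain maximum-likelihood logistic fit on an explicit design matrix."""

    params: pd.Series
    pvalues: pd.Series
    llf: float
    n_iter: int
    design_columns: tuple[str, ...]

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    def linear_predictor(self, design: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(design[list(self.design_columns)], has_constant="add")
        return np.asarray(X @ self.params.reindex(X.columns))


def _ml_fit(design: pd.DataFrame, y: np.ndarray, max_iter: int = 200) -> LogisticFit:
    import warnings

    X = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(np.asarray(X, dtype=float)) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (duplicated or constant column)")
    model = sm.Logit(np.asarray(y, dtype=float), np.asarray(X, dtype=float))
    with warnings.catch_warnings():
        # convergence and separation are handled explicitly below
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=max_iter, method="newton")
            if not res.mle_retvals.get("converged", False):
                raise RuntimeError("newton did not converge")
        except Exception:
            # Newton oscillates or hits a singular Hessian on
            # near-separated data; quasi-Newton is more forgiving, and a
            # genuinely diverging coefficient is still caught below.
            try:
                res = model.fit(disp=0, maxiter=max_iter, method="lbfgs")
            except Exception as exc:
                raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(
            f"logistic fit did not converge in {max_iter} iterations"
        )
    if np.max(np.abs(res.params)) > 50:
        big = X.columns[int(np.argmax(np.abs(res.params)))]
        raise SeparationError(f"coefficient diverged for term {big!r} (separation?)")
    yv = np.asarray(y, dtype=float)
    fitted = np.asarray(res.predict())
    if np.all(fitted[yv == 1] > 1 - 1e-4) and np.all(fitted[yv == 0] < 1e-4):
        raise SeparationError("complete separation: the model predicts the outcome perfectly")
    params = pd.Series(res.params, index=X.columns)
    pvalues = pd.Series(res.pvalues, index=X.columns)
    return LogisticFit(
        params=params,
        pvalues=pvalues,
        llf=float(res.llf),
        n_iter=int(res.mle_retvals.get("iterations", max_iter)),
        design_columns=tuple(design.columns),
    )


def fit_logistic(
    design: pd.DataFrame,
    y: np.ndarray,
    retention_alpha: float = 0.30,
    force_include: tuple[str, ...] = (),
    max_iter: int = 200,
) -> LogisticFit:
    """Backward-eliminated logistic fit on a ready-made design matrix.

    Repeatedly removes the least significant term (largest Wald p-value
    at or above ``retention_alpha``), refitting after each removal; terms
    in ``force_include`` are never removed.
    """
    if len(design) <= design.shape[1]:
        raise ValueError("more design terms than observations")
    current = design.copy()
    while True:
        fit = _ml_fit(current, y, max_iter)
        removable = [c for c in current.columns if c not in force_include]
        if not removable:
            return fit
        # a NaN Wald p (singular Hessian for that term) is treated as
        # uninformative and removed first
        pv = fit.pvalues[removable].fillna(1.0)
        worst = pv.idxmax()
        if pv[worst] < retention_alpha:
            return fit
        current = current.drop(columns=[worst])
        if current.shape[1] == 0:
            return _ml_fit(current, y, max_iter)


def _fp1_candidates() -> list[tuple[float, ...]]:
    return [(p,) for p in FP_POWERS]


def _fp2_candidates() -> list[tuple[float, ...]]:
    pairs = [
        (p1, p2) for i, p1 in enumerate(FP_POWERS) for p2 in FP_POWERS[i:]
    ]
    return pairs  # 36 distinct-or-equal ordered pairs incl. 8 repeated


def select_fp(
    covariates: pd.DataFrame,
    age: pd.Series,
    y: np.ndarray,
    alpha: float = 0.05,
    scale: float = 100.0,
    max_iter: int = 200,
) -> tuple[float, ...] | None:
    """Closed-test fractional-polynomial selection for the age effect.

    Adjusting for ``covariates``, picks the best FP1 and FP2 age transforms
    by deviance and runs the standard closed test: FP2 against no age term
    (4 df), FP2 against linear age (3 df), FP2 against FP1 (2 df), stopping
    at the first non-significant comparison.  Returns ``None`` (no age
    effect), ``(1.0,)`` (linear), a single power (FP1) or a pair (FP2).
    """

    def dev(powers: tuple[float, ...] | None) -> float:
        design = covariates.copy()
        if powers is not None:
            design = pd.concat([design, _fp_frame(age, powers, scale)], axis=1)
        return _ml_fit(design, y, max_iter).deviance

    def best(candidates: list[tuple[float, ...]]):
        # candidate transforms that fail to fit (quasi-separation on an
        # extreme power) are simply excluded from the search
        scored = []
        for powers in candidates:
            try:
                scored.append((dev(powers), powers))
            except (SeparationError, RuntimeError):
                continue
        if not scored:
            return np.inf, None
        return min(scored, key=lambda t: t[0])

    d_null = dev(None)
    d_linear = dev((1.0,))
    d_fp1, fp1 = best(_fp1_candidates())
    d_fp2, fp2 = best(_fp2_candidates())

    def significant(d_bigger_model: float, d_smaller_model: float, df: int) -> bool:
        lr = max(d_smaller_model - d_bigger_model, 0.0)
        return stats.chi2.sf(lr, df) < alpha

    if fp2 is not None:
        if not significant(d_fp2, d_null, 4):
            return None
        if not significant(d_fp2, d_linear, 3):
            return (1.0,)
        if fp1 is None or not significant(d_fp2, d_fp1, 2):
            return fp1 if fp1 is not None else fp2
        return fp2
    if fp1 is not None:  # degenerate: no FP2 model fit; close over FP1
        if not significant(d_fp1, d_null, 2):
            return None
        return (1.0,) if not significant(d_fp1, d_linear, 1) else fp1
    return (1.0,) if significant(d_linear, d_null, 1) else None


class FractionalPolynomialLogisticRegression(BaseEstimator):
    """Logistic risk model with FP age terms and permissive backward selection.

    Parameters
    ----------
    predictors : list of str, optional
        Covariate columns entering linearly (binary flags or counts).
        Defaults to every column except identifiers, the outcome and age.
    age_col : str
        Column holding age in years; set to ``None`` to omit any age term.
    fp_powers : "auto", tuple or None
        ``"auto"`` runs the closed-test selection; a tuple fixes the
        transform (e.g. ``(2.0, 3.0)``); ``None`` uses linear age.
    retention_alpha : float
        Wald p-value threshold for backward elimination (terms with
        p >= threshold are dropped).  Deliberately large by default so
        weak but informative predictors survive.
    fp_alpha : float
        Significance level of the FP closed test.
    force_include : tuple of str
        Covariates never dropped by elimination.

    Attributes
    ----------
    intercept_ : float
    coef_ : pandas Series of retained term coefficients (log-odds ratios)
    powers_ : chosen FP powers (tuple or None)
    pvalues_ : Wald p-values of the final fit
    shrinkage_ : uniform shrinkage factor applied to ``coef_`` (1.0 = none)
    n_iter_ : Newton iterations of the final fit
    """

    def __init__(
        self,
        predictors: list[str] | None = None,
        age_col: str | None = "age",
        fp_powers="auto",
        retention_alpha: float = 0.30,
        fp_alpha: float = 0.05,
        force_include: tuple[str, ...] = (),
        age_scale: float = 100.0,
        max_iter: int = 200,
    ) -> None:
        self.predictors = predictors
        self.age_col = age_col
        self.fp_powers = fp_powers
        self.retention_alpha = retention_alpha
        self.fp_alpha = fp_alpha
        self.force_include = force_include
        self.age_scale = age_scale
        self.max_iter = max_iter

    # -- design construction -------------------------------------------------
    def _covariate_columns(self, X: pd.DataFrame) -> list[str]:
        if self.predictors is not None:
            return list(self.predictors)
        drop = set(NON_PREDICTOR_COLUMNS) | {self.age_col}
        return [c for c in X.columns if c not in drop]

    def _design(self, X: pd.DataFrame, powers, columns: list[str]) -> pd.DataFrame:
        design = X[columns].astype(float)
        if self.age_col is not None and powers is not None:
            fp = _fp_frame(X[self.age_col], powers, self.age_scale)
            design = pd.concat([fp, design], axis=1)
        return design

    # -- estimator API --------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "FractionalPolynomialLogisticRegression":
        if y is None:
            if "outcome" not in X.columns:
                raise ValueError("y not given and no 'outcome' column present")
            y = X["outcome"]
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        covs = self._covariate_columns(X)
        # constant columns carry no information (common in bootstrap
        # resamples of rare flags) and are silently excluded from this fit
        covs = [c for c in covs if X[c].nunique() > 1]

        if self.age_col is None:
            powers = None
        elif self.fp_powers == "auto":
            powers = select_fp(
                X[covs].astype(float), X[self.age_col], y,
                alpha=self.fp_alpha, scale=self.age_scale, max_iter=self.max_iter,
            )
        else:
            powers = self.fp_powers

        design = self._design(X, powers, covs)
        age_terms = tuple(c for c in design.columns if c.startswith("age_fp("))
        fit = fit_logistic(
            design, y,
            retention_alpha=self.retention_alpha,
            force_include=tuple(self.force_include) + age_terms,
            max_iter=self.max_iter,
        )
        self.powers_ = powers
        self.columns_ = list(fit.design_columns)
        self.intercept_ = float(fit.params["const"])
        self.coef_ = fit.params.drop("const")
        self.pvalues_ = fit.pvalues.drop("const")
        self.llf_ = fit.llf
        self.n_iter_ = fit.n_iter
        self.shrinkage_ = 1.0
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(covs)
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        covs = [c for c in self.columns_ if not c.startswith("age_fp(")]
        design = self._design(X, self.powers_, covs)[self.columns_]
        return self.intercept_ + np.asarray(design @ self.coef_.reindex(self.columns_))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # -- serialization --------------------------------------------------------
    def to_document(self) -> dict:
        """Versioned JSON-serializable description of the fitted model."""
        return {
            "format": "prismor-model/1",
            "intercept": self.intercept_,
            "terms": [
                {"name": name, "coefficient": float(self.coef_[name])}
                for name in self.columns_
            ],
            "fp_powers": list(self.powers_) if self.powers_ else None,
            "age_scale": self.age_scale,
            "retention_alpha": self.retention_alpha,
            "shrinkage_factor": self.shrinkage_,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_document(), fh, indent=2)
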