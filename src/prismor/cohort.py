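"""Seeded synthetic cohorts of adult inpatient admissions.

The generator emulates the marginal structure of a prospective adult
inpatient cohort: ages drawn from a truncated skew-normal targeting
median 68 (IQR 57-80), independent binary admission covariates at fixed
prevalences, a right-skewed zero-inflated negative-binomial count of
prescribed drugs, and independent ATC drug-class indicator flags.  The
binary study outcome (>= 1 clinically significant medication error) is then
assigned from a configurable *true* logistic model, so downstream fitting,
validation and triage simulations have a known ground truth.

Covariates are generated independently by default; a ``copula_rho`` hook
can induce a Gaussian-copula correlation between age and drug count, but
no joint structure is asserted beyond the marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .published import PUBLISHED_COEFFICIENTS, PUBLISHED_INTERCEPT

#: Default prevalence of each binary covariate (cohort marginals).
DEFAULT_PREVALENCES: dict[str, float] = {
    "male": 0.524,
    "treatment_before_admission": 0.922,
    "bpmh_available": 0.548,
    "prior_hosp_30d": 0.117,
    "transfer_72h": 0.024,
    "admission_from_ed": 0.134,
    "admission_from_outside": 0.022,
    "night_admission": 0.178,
    "weekend_admission": 0.092,
    "surgical_admission": 0.252,
}

#: Default marginal probabilities of carrying >= 1 drug of each ATC class.
DEFAULT_ATC_PROBABILITIES: dict[str, float] = {
    "atc_B01": 0.35,
    "atc_J01": 0.20,
    "atc_N05": 0.25,
    "atc_B05": 0.30,
    "atc_N02": 0.40,
}


@dataclass(frozen=True)
class AgeDistribution:
    """Truncated skew-normal age model (years).

    Defaults were fitted once so the quartiles of the [18, 105]-truncated
    distribution equal 57/68/80.
    """

    skew: float = 2.071
    loc: float = 51.484
    scale: float = 26.622
    lower: float = 18.0
    upper: float = 105.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n)
        have = 0
        while have < n:
            draw = stats.skewnorm.rvs(
                self.skew, loc=self.loc, scale=self.scale,
                size=max(n - have, 16), random_state=rng,
            )
            keep = draw[(draw >= self.lower) & (draw <= self.upper)]
            take = min(len(keep), n - have)
            out[have : have + take] = keep[:take]
            have += take
        return np.round(out, 1)


@dataclass(frozen=True)
class DrugCountDistribution:
    """Zero-inflated negative binomial for the number of prescribed drugs.

    ``pi`` is the structural-zero probability (admissions with no home
    medication), ``mu``/``size`` the negative-binomial mean and dispersion.
    Defaults were calibrated once by simulation so that, combined with the
    reference outcome model, the cohort outcome prevalence is ~25.9%.
    """

    pi: float = 0.20
    mu: float = 3.0
    size: float = 1.6

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.size / (self.size + self.mu)
        counts = rng.negative_binomial(self.size, p, size=n)
        zero = rng.random(n) < self.pi
        counts[zero] = 0
        return counts


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for a synthetic cohort."""

    n_patients: int = 1408
    age: AgeDistribution = field(default_factory=AgeDistribution)
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    atc_class_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATC_PROBABILITIES)
    )
    drug_count: DrugCountDistribution = field(default_factory=DrugCountDistribution)
    copula_rho: float = 0.0  # optional age/drug-count Gaussian-copula link
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        for name, p in {**self.covariate_prevalences, **self.atc_class_probabilities}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]: {p}")
        if not -1.0 < self.copula_rho < 1.0:
            raise ValueError("copula_rho must lie in (-1, 1)")
        if self.age.lower < 18:
            raise ValueError("cohort admits adults only (age >= 18)")

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrueOutcomeModel:
    """True logistic data-generating model for the binary outcome.

    ``coefficients`` maps design-term names to log-odds ratios.  The two
    age terms use the fractional-polynomial convention ``(age/100)**2`` and
    ``(age/100)**3``; every other term must be a cohort column.
    """

    intercept: float = PUBLISHED_INTERCEPT
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(PUBLISHED_COEFFICIENTS)
    )
    age_scale: float = 100.0

    def linear_predictor(self, cohort: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(cohort), self.intercept, dtype=float)
        a = np.asarray(cohort["age"], dtype=float) / self.age_scale
        for term, beta in self.coefficients.items():
            if term == "age_fp2":
                lp += beta * a**2
            elif term == "age_fp3":
                lp += beta * a**3
            elif term in cohort.columns:
                lp += beta * np.asarray(cohort[term], dtype=float)
            else:
                raise KeyError(f"model term {term!r} not a cohort column")
        return lp

    def probabilities(self, cohort: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(cohort))


def cohort_spec_from_yaml(path) -> CohortSpec:
    """Build a CohortSpec from a YAML file.

    Top-level keys mirror the dataclass fields; ``age`` and ``drug_count``
    are nested mappings of their distribution parameters.  Omitted keys
    keep the package defaults.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    if "age" in data:
        kwargs["age"] = AgeDistribution(**data.pop("age"))
    if "drug_count" in data:
        kwargs["drug_count"] = DrugCountDistribution(**data.pop("drug_count"))
    spec = CohortSpec(**kwargs, **data)
    spec.validate()
    return spec


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Generate a cohort table of admissions; deterministic given (spec, seed)."""
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_patients
    data: dict[str, np.ndarray] = {"patient_id": np.arange(1, n + 1)}
    if spec.copula_rho:
        # Gaussian copula between age and drug count: draw correlated normals,
        # map through each marginal's empirical quantile function.
        z = rng.multivariate_normal(
            [0, 0], [[1, spec.copula_rho], [spec.copula_rho, 1]], size=n
        )
        u_age, u_drug = stats.norm.cdf(z[:, 0]), stats.norm.cdf(z[:, 1])
        ages = np.sort(spec.age.sample(n, rng))[
            np.clip((u_age * n).astype(int), 0, n - 1)
        ]
        drugs = np.sort(spec.drug_count.sample(n, rng))[
            np.clip((u_drug * n).astype(int), 0, n - 1)
        ]
        data["age"], data["n_drugs"] = ages, drugs
    else:
        data["age"] = spec.age.sample(n, rng)
        data["n_drugs"] = spec.drug_count.sample(n, rng)
    for name, p in spec.covariate_prevalences.items():
        data[name] = (rng.random(n) < p).astype(int)
    for name, p in spec.atc_class_probabilities.items():
        data[name] = (rng.random(n) < p).astype(int)
    return pd.DataFrame(data)


def assign_outcomes(
    cohort: pd.DataFrame,
    model: TrueOutcomeModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the binary outcome per patient as Bernoulli(p_i) under ``model``."""
    model = model or TrueOutcomeModel()
    rng = np.random.default_rng(seed)
    p = model.probabilities(cohort)
    out = cohort.copy()
    out["outcome"] = (rng.random(len(cohort)) < p).astype(int)
    return out


def generate_me_records(
    cohort_with_outcome: pd.DataFrame,
    seed: int = 0,
    severity_probs: dict[str, float] | None = None,
    mean_extra_significant: float = 0.30,
    c_rate: float = 0.095,
    day_geom_p: float = 0.45,
) -> pd.DataFrame:
    """Medication-error-level records consistent with a cohort's outcomes.

    Every outcome-positive patient receives ``1 + Poisson(mean_extra)``
    significant MEs with severities drawn from ``severity_probs`` (defaults
    to the observed event-of-interest mix: D 315/475, E+ 157/475, actual
    harm 3/475).  Non-harmful category-C errors occur Poisson(``c_rate``)
    per patient regardless of outcome.  Hospitalization day is geometric
    starting at 1, putting the mode on the first day.
    """
    sev = severity_probs or {"D": 315 / 475, "E+": 157 / 475, "H": 3 / 475}
    codes, probs = list(sev), np.array(list(sev.values()))
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for pid, outcome in zip(
        cohort_with_outcome["patient_id"], cohort_with_outcome["outcome"]
    ):
        if outcome:
            k = 1 + rng.poisson(mean_extra_significant)
            for s in rng.choice(codes, size=k, p=probs):
                rows.append((pid, s, int(rng.geometric(day_geom_p))))
        for _ in range(rng.poisson(c_rate)):
            rows.append((pid, "C", int(rng.geometric(day_geom_p))))
    return pd.DataFrame(rows, columns=["patient_id", "severity", "day"])


def reference_me_fixture(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort + ME records reproducing the reference study's exact counts.

    Returns a 1,408-admission cohort in which exactly 365 patients carry
    the 475 events of interest (3 actual harm, 157 E+, 315 D) and 134
    category-C errors are spread at random, mirroring the severity table
    of the source cohort.  Which patients are positive is random (seeded);
    only the counts are pinned.
    """
    spec = CohortSpec(n_patients=1408, seed=seed)
    cohort = generate_cohort(spec)
    rng = np.random.default_rng(seed + 1)
    positive_ids = rng.choice(cohort["patient_id"], size=365, replace=False)
    severities = np.array(["H"] * 3 + ["E+"] * 157 + ["D"] * 315)
    rng.shuffle(severities)
    # one significant ME per positive patient, remaining 110 spread at random
    owners = np.concatenate(
        [positive_ids, rng.choice(positive_ids, size=475 - 365, replace=True)]
    )
    days = rng.geometric(0.45, size=475 + 134)
    rows = list(zip(owners, severities, days[:475]))
    c_owners = rng.choice(cohort["patient_id"], size=134, replace=True)
    rows += list(zip(c_owners, ["C"] * 134, days[475:]))
    records = pd.DataFrame(rows, columns=["patient_id", "severity", "day"])
    records["patient_id"] = records["patient_id"].astype(int)
    records["day"] = records["day"].astype(int)
    return cohort, records
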