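"""Univariate eligibility screening and association-rule mining.

Candidate predictors are screened with deliberately permissive univariate
tests (Wilcoxon-Mann-Whitney for continuous variables, Yates-corrected
chi-square for binary ones; eligibility at p < 0.50), while the relation
between ATC drug classes and the endpoint is explored by association-rule
mining with a minimum support of 5% and a minimum confidence of 10%.

The rule miner is an exact enumerator: the consequent is always the
endpoint, antecedents are subsets of the ATC indicator columns up to a
configurable size (default 2), and every qualifying rule is returned in a
deterministic order (support descending, then lexicographic antecedent).
With a handful of drug-class indicators exhaustive enumeration is exact
and fast, so no frequent-itemset machinery is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ScreeningConfig:
    eligibility_alpha: float = 0.50
    min_support: float = 0.05
    min_confidence: float = 0.10
    max_antecedent: int = 2

    def __post_init__(self) -> None:
        for name in ("eligibility_alpha", "min_support", "min_confidence"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]: {v}")
        if self.max_antecedent < 1:
            raise ValueError("max_antecedent must be >= 1")


@dataclass(frozen=True)
class AssociationRule:
    """antecedent (set of ATC classes) -> endpoint, with support/confidence."""

    antecedent: frozenset[str]
    consequent: str
    support: float
    confidence: float

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise ValueError("antecedent must be non-empty")


def univariate_screen(
    cohort: pd.DataFrame,
    variable: str,
    outcome: str = "outcome",
    alpha: float = 0.50,
) -> tuple[float, bool]:
    """Univariate p-value for one variable and its eligibility flag.

    Binary variables use the chi-square test on the 2x2 table with Yates
    continuity correction; any other numeric variable uses the two-sided
    Wilcoxon-Mann-Whitney test (normal approximation, tie-corrected).
    A constant variable has no defined p-value and is flagged ineligible.
    """
    y = np.asarray(cohort[outcome])
    x = np.asarray(cohort[variable])
    if len(np.unique(x)) < 2:
        import warnings

        warnings.warn(f"variable {variable!r} is constant; excluded", stacklevel=2)
        return float("nan"), False
    values = np.unique(x)
    if len(values) == 2:
        table = np.array(
            [[np.sum((x == v) & (y == 0)), np.sum((x == v) & (y == 1))] for v in values]
        )
        _, p, _, _ = stats.chi2_contingency(table, correction=True)
    else:
        p = stats.mannwhitneyu(
            x[y == 1], x[y == 0], alternative="two-sided", method="asymptotic"
        ).pvalue
    return float(p), bool(p < alpha)


def screen_cohort(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    outcome: str = "outcome",
    config: ScreeningConfig | None = None,
) -> pd.DataFrame:
    """Screening report: one row per variable with test, p-value, eligibility."""
    config = config or ScreeningConfig()
    rows = []
    for var in variables:
        n_levels = cohort[var].nunique()
        test = "chi-square (Yates)" if n_levels == 2 else "Wilcoxon-Mann-Whitney"
        p, eligible = univariate_screen(
            cohort, var, outcome=outcome, alpha=config.eligibility_alpha
        )
        rows.append({"variable": var, "test": test, "p_value": p, "eligible": eligible})
    return pd.DataFrame(rows)


def transactions_from_cohort(
    cohort: pd.DataFrame,
    atc_columns: Iterable[str] | None = None,
    outcome: str = "outcome",
    endpoint_label: str = "ME",
) -> list[frozenset[str]]:
    """Per-patient itemsets of carried ATC classes plus the endpoint label."""
    if atc_columns is None:
        atc_columns = [c for c in cohort.columns if c.startswith("atc_")]
    cols = list(atc_columns)
    out: list[frozenset[str]] = []
    for _, row in cohort[cols + [outcome]].iterrows():
        items = {c for c in cols if row[c]}
        if row[outcome]:
            items.add(endpoint_label)
        out.append(frozenset(items))
    return out


def mine_rules(
    transactions: Sequence[frozenset[str]],
    config: ScreeningConfig | None = None,
    endpoint_label: str = "ME",
) -> list[AssociationRule]:
    """All rules {ATC classes} -> endpoint meeting support and confidence.

    support = P(antecedent and endpoint co-occur); confidence = P(endpoint |
    antecedent).  Exhaustive over antecedents up to ``max_antecedent`` items;
    order-invariant in the transactions and deterministically sorted.
    """
    config = config or ScreeningConfig()
    n = len(transactions)
    if n == 0:
        return []
    items = sorted(set().union(*transactions) - {endpoint_label})
    rules = []
    for size in range(1, config.max_antecedent + 1):
        for ante in combinations(items, size):
            ante_set = frozenset(ante)
            n_ante = sum(ante_set <= t for t in transactions)
            if n_ante == 0:
                continue
            n_both = sum(
                ante_set <= t and endpoint_label in t for t in transactions
            )
            support = n_both / n
            confidence = n_both / n_ante
            if support >= config.min_support and confidence >= config.min_confidence:
                rules.append(
                    AssociationRule(ante_set, endpoint_label, support, confidence)
                )
    rules.sort(key=lambda r: (-r.support, tuple(sorted(r.antecedent))))
    return rules


def select_candidate_classes(rules: Iterable[AssociationRule]) -> set[str]:
    """Union of antecedent drug classes across retained rules."""
    out: set[str] = set()
    for rule in rules:
        out |= rule.antecedent
    return out
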