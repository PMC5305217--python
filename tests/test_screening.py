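"""Univariate screening and association-rule mining, with brute-force oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prismor.screening import (
    AssociationRule,
    ScreeningConfig,
    mine_rules,
    select_candidate_classes,
    transactions_from_cohort,
    univariate_screen,
)


def cohort_from_2x2(n00, n01, n10, n11, var="male"):
    """Cohort with a binary variable and outcome in the given cell counts."""
    rows = (
        [(0, 0)] * n00 + [(0, 1)] * n01 + [(1, 0)] * n10 + [(1, 1)] * n11
    )
    return pd.DataFrame(rows, columns=[var, "outcome"])


def test_sex_table_reproduces_published_p_value():
    """Yates-corrected chi-square on the sex 2x2 gives p = 0.119."""
    cohort = cohort_from_2x2(483, 187, 560, 178)
    p, eligible = univariate_screen(cohort, "male")
    assert round(p, 3) == 0.119
    assert eligible  # 0.119 < 0.50


def test_chi_square_matches_contingency_formula():
    """Small 2x2 agrees with direct evaluation of the corrected statistic."""
    from scipy.stats import chi2

    n00, n01, n10, n11 = 20, 5, 12, 13
    cohort = cohort_from_2x2(n00, n01, n10, n11)
    p, _ = univariate_screen(cohort, "male")
    table = np.array([[n00, n01], [n10, n11]], dtype=float)
    n = table.sum()
    row, col = table.sum(1), table.sum(0)
    expected = np.outer(row, col) / n
    stat = ((np.abs(table - expected) - 0.5) ** 2 / expected).sum()
    assert p == pytest.approx(float(chi2.sf(stat, 1)), abs=1e-10)


def test_continuous_variable_uses_rank_test():
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(0)
    cohort = pd.DataFrame(
        {"age": rng.normal(65, 10, 300).round(), "outcome": rng.integers(0, 2, 300)}
    )
    p, _ = univariate_screen(cohort, "age")
    ref = mannwhitneyu(
        cohort.loc[cohort.outcome == 1, "age"],
        cohort.loc[cohort.outcome == 0, "age"],
        alternative="two-sided",
        method="asymptotic",
    ).pvalue
    assert p == pytest.approx(float(ref), abs=1e-12)


def test_balanced_variable_is_not_excluded():
    cohort = cohort_from_2x2(50, 50, 50, 50)
    p, eligible = univariate_screen(cohort, "male")
    assert p > 0.99
    assert not eligible


def test_constant_variable_flagged():
    cohort = pd.DataFrame({"flat": np.zeros(20), "outcome": [0, 1] * 10})
    with pytest.warns(UserWarning):
        p, eligible = univariate_screen(cohort, "flat")
    assert np.isnan(p) and not eligible


# --- rule mining ------------------------------------------------------------


def brute_force_rules(transactions, config, endpoint="ME"):
    """Independent enumeration over every antecedent subset."""
    items = sorted(set().union(*transactions) - {endpoint})
    out = []
    for size in range(1, config.max_antecedent + 1):
        for ante in combinations(items, size):
            a = frozenset(ante)
            n_a = sum(a <= t for t in transactions)
            n_ae = sum(a <= t and endpoint in t for t in transactions)
            if n_a == 0:
                continue
            if n_ae / len(transactions) >= config.min_support and n_ae / n_a >= config.min_confidence:
                out.append((a, n_ae / len(transactions), n_ae / n_a))
    return sorted(out, key=lambda r: (-r[1], tuple(sorted(r[0]))))


TEN_TRANSACTIONS = [
    frozenset(s)
    for s in [
        {"B01", "N05", "ME"}, {"B01", "ME"}, {"B01"}, {"N05", "J01", "ME"},
        {"J01"}, {"B05", "ME"}, {"B05", "N02"}, {"N02", "ME"},
        {"B01", "N05"}, set(),
    ]
]


def test_rules_equal_bruteforce_enumeration():
    config = ScreeningConfig(min_support=0.1, min_confidence=0.3)
    mined = mine_rules(TEN_TRANSACTIONS, config)
    oracle = brute_force_rules(TEN_TRANSACTIONS, config)
    assert [(r.antecedent, r.support, r.confidence) for r in mined] == oracle


def test_rules_invariant_to_transaction_order(rng):
    config = ScreeningConfig(min_support=0.1, min_confidence=0.2)
    shuffled = list(TEN_TRANSACTIONS)
    rng.shuffle(shuffled)
    assert mine_rules(shuffled, config) == mine_rules(TEN_TRANSACTIONS, config)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    s1=st.floats(0.05, 0.5), s2=st.floats(0.05, 0.5),
    c1=st.floats(0.05, 0.9), c2=st.floats(0.05, 0.9),
)
def test_raising_thresholds_never_adds_rules(s1, s2, c1, c2):
    lo = ScreeningConfig(min_support=min(s1, s2), min_confidence=min(c1, c2))
    hi = ScreeningConfig(min_support=max(s1, s2), min_confidence=max(c1, c2))
    rules_lo = {r.antecedent for r in mine_rules(TEN_TRANSACTIONS, lo)}
    rules_hi = {r.antecedent for r in mine_rules(TEN_TRANSACTIONS, hi)}
    assert rules_hi <= rules_lo


def test_support_above_max_frequency_gives_nothing():
    assert mine_rules(TEN_TRANSACTIONS, ScreeningConfig(min_support=0.99)) == []
    assert mine_rules([], ScreeningConfig()) == []


def test_single_dominant_item_rule():
    transactions = [frozenset({"B01", "ME"})] * 6 + [frozenset({"B01"})] * 4
    rules = mine_rules(transactions, ScreeningConfig(min_support=0.05, min_confidence=0.10))
    top = rules[0]
    assert top.antecedent == frozenset({"B01"})
    assert top.support == pytest.approx(0.6)
    assert top.confidence == pytest.approx(0.6)


def test_five_reference_classes_recovered_on_designed_fixture():
    """A cohort built so exactly B01, J01, N05, B05, N02 pass both thresholds."""
    rng = np.random.default_rng(99)
    n = 2000
    cohort = pd.DataFrame({f"atc_{c}": rng.random(n) < p for c, p in
                           [("B01", 0.35), ("J01", 0.2), ("N05", 0.25),
                            ("B05", 0.3), ("N02", 0.4), ("R03", 0.01)]})
    cohort = cohort.astype(int)
    cohort["outcome"] = (rng.random(n) < 0.26).astype(int)
    rules = mine_rules(
        transactions_from_cohort(cohort), ScreeningConfig(max_antecedent=1)
    )
    assert select_candidate_classes(rules) == {
        "atc_B01", "atc_J01", "atc_N05", "atc_B05", "atc_N02"
    }


def test_candidate_classes_are_set_union():
    r1 = AssociationRule(frozenset({"a"}), "ME", 0.2, 0.5)
    r2 = AssociationRule(frozenset({"a", "b"}), "ME", 0.1, 0.4)
    assert select_candidate_classes([r1, r2, r1]) == {"a", "b"}
    assert select_candidate_classes([]) == set()
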