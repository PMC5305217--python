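"""NCC MERP-based severity grading and the study endpoint.

Medication errors (MEs) are graded on the NCC MERP index collapsed to
three analysis categories plus the rare errors that reached the patient:

* ``C`` — no potential harm (not an event of interest),
* ``D`` — requires monitoring or intervention to preclude harm,
* ``E+`` — potential harm (NCC MERP E and above),
* ``H`` — actual harm (adverse drug event).

The study endpoint is patient-level: 1 if the patient had at least one ME
of category D or above at any time during the stay.  Actual-harm errors are
kept as their own bucket in tabulations but always count as events of
interest and pool with E+ conceptually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical severity codes, most severe last.
SEVERITY_CODES: tuple[str, ...] = ("C", "D", "E+", "H")

#: Severities that make an ME an event of interest (clinically significant).
SIGNIFICANT_SEVERITIES: frozenset[str] = frozenset({"D", "E+", "H"})


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"patient_id", "severity", "day"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"ME records missing columns: {sorted(missing)}")
    bad = set(records["severity"].unique()) - set(SEVERITY_CODES)
    if bad:
        raise ValueError(f"unknown severity codes: {sorted(bad)}")
    if len(records) and (records["day"] < 1).any():
        raise ValueError("hospitalization day must be >= 1")
    return records


@dataclass
class SeverityTabulation:
    """Counts and shares of medication errors by severity category."""

    counts: dict[str, int]
    total: int
    events_of_interest: int
    percentages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("severity counts do not sum to total")
        if not self.percentages and self.total:
            self.percentages = {
                k: 100.0 * v / self.total for k, v in self.counts.items()
            }


def tabulate_severity(records: pd.DataFrame) -> SeverityTabulation:
    """Tabulate ME records by severity; events of interest are D, E+ and H."""
    _validate_records(records)
    counts = {code: int((records["severity"] == code).sum()) for code in SEVERITY_CODES}
    total = int(len(records))
    events = sum(counts[c] for c in SIGNIFICANT_SEVERITIES)
    return SeverityTabulation(counts=counts, total=total, events_of_interest=events)


def derive_endpoint(
    cohort: pd.DataFrame, records: pd.DataFrame, strict: bool = False
) -> pd.DataFrame:
    """Attach the binary study endpoint to a cohort.

    ``outcome`` is 1 iff the patient has at least one record of severity D
    or above.  Records whose ``patient_id`` is absent from the cohort are
    ignored with a warning (or raise in ``strict`` mode).
    """
    _validate_records(records)
    ids = set(cohort["patient_id"])
    orphan = ~records["patient_id"].isin(ids)
    if orphan.any():
        msg = f"{int(orphan.sum())} ME records reference unknown patients"
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
        records = records[~orphan]
    significant = records[records["severity"].isin(SIGNIFICANT_SEVERITIES)]
    positives = set(significant["patient_id"])
    out = cohort.copy()
    out["outcome"] = cohort["patient_id"].isin(positives).astype(int)
    return out


def day_histogram(records: pd.DataFrame, significant_only: bool = True) -> dict[int, int]:
    """Counts of MEs per hospitalization day (events of interest by default)."""
    _validate_records(records)
    if significant_only:
        records = records[records["severity"].isin(SIGNIFICANT_SEVERITIES)]
    counts = records["day"].value_counts().sort_index()
    return {int(day): int(n) for day, n in counts.items()}
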