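"""Cohort and medication-error table readers/writers (headered CSV).

One row per admission in the cohort table; one row per medication error in
the ME table.  All flags are 0/1 integers.  Validation is row-level: in
strict mode a bad row aborts with its position, otherwise offending rows
are dropped with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .grading import SEVERITY_CODES

#: Mandatory cohort columns and their kinds.
COHORT_SCHEMA: dict[str, str] = {
    "patient_id": "id",
    "age": "continuous",
    "male": "flag",
    "n_drugs": "count",
    "atc_B01": "flag",
    "atc_J01": "flag",
    "atc_N05": "flag",
    "atc_B05": "flag",
    "atc_N02": "flag",
    "treatment_before_admission": "flag",
    "bpmh_available": "flag",
    "prior_hosp_30d": "flag",
    "transfer_72h": "flag",
    "admission_from_ed": "flag",
    "admission_from_outside": "flag",
    "night_admission": "flag",
    "weekend_admission": "flag",
    "surgical_admission": "flag",
}


def _bad_rows(df: pd.DataFrame) -> pd.Series:
    bad = pd.Series(False, index=df.index)
    if "age" in df:
        bad |= df["age"].isna() | (df["age"] < 18)
    if "n_drugs" in df:
        bad |= df["n_drugs"].isna() | (df["n_drugs"] < 0)
    for col, kind in COHORT_SCHEMA.items():
        if kind == "flag" and col in df:
            bad |= ~df[col].isin([0, 1])
    if "outcome" in df:
        bad |= ~df["outcome"].isin([0, 1])
    return bad


def load_cohort(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV (header case-insensitive)."""
    df = pd.read_csv(path)
    df.columns = [c.lower() if c.lower() in COHORT_SCHEMA else c for c in df.columns]
    missing = [c for c in COHORT_SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing mandatory columns: {missing}")
    bad = _bad_rows(df)
    if bad.any():
        lines = [i + 2 for i in df.index[bad][:10]]  # +2: header + 1-based
        msg = f"{int(bad.sum())} invalid cohort rows (file lines {lines} ...)"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + "; dropped", stacklevel=2)
        df = df[~bad].reset_index(drop=True)
    return df


def save_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def load_me_records(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read a medication-error table with columns patient_id, severity, day."""
    df = pd.read_csv(path)
    missing = {"patient_id", "severity", "day"} - set(df.columns)
    if missing:
        raise ValueError(f"ME file missing columns: {sorted(missing)}")
    bad = ~df["severity"].isin(SEVERITY_CODES) | (df["day"] < 1)
    if bad.any():
        msg = f"{int(bad.sum())} invalid ME rows"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + "; dropped", stacklevel=2)
        df = df[~bad].reset_index(drop=True)
    return df
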