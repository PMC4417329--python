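"""Reading of patient and dispensing tables; exposure-window filtering.

The cohort is adults (age >= 20 at the index date) registered with a
practice; dispensing records are one row per dispensed item. Exposure is
defined by an 84-day look-back window ending on (and including) the
index date: 84 days is chosen because the most common repeat
prescription length is 56 days (range 28-84), so an 84-day window is the
most reliable indicator of current drug exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import pandas as pd

from .formulary import _read_delimited

__all__ = [
    "Patient",
    "IngestError",
    "SEX_LEVELS",
    "URBAN_RURAL_LEVELS",
    "read_patients",
    "read_dispensing",
    "window_filter",
]

logger = logging.getLogger(__name__)

SEX_LEVELS = ("M", "F")
URBAN_RURAL_LEVELS = ("primary_city", "urban", "accessible", "remote")

MIN_COHORT_AGE = 20


class IngestError(ValueError):
    """Raised for structurally invalid patient/dispensing input."""


@dataclass(frozen=True)
class Patient:
    patient_id: str
    age_at_index: int
    sex: str  # M / F
    simd_quintile: int  # 1 (affluent) .. 5 (deprived)
    urban_rural: str
    care_home: bool
    practice_id: str


def read_patients(path: str | Path) -> pd.DataFrame:
    """Read the patient demographics table.

    Returns a DataFrame with columns ``patient_id, age, sex,
    simd_quintile, urban_rural, care_home, practice_id`` and typed
    columns. Rows violating the cohort definition (age < 20) or missing a
    practice are dropped with a logged reason and counted in
    ``df.attrs["n_rejected"]``; rows with labels outside the known
    category sets are validation errors.
    """
    df = _read_delimited(Path(path))
    required = {
        "patient_id", "age", "sex", "simd_quintile",
        "urban_rural", "care_home", "practice_id",
    }
    if not required.issubset(df.columns):
        raise IngestError(
            f"patient file missing columns {sorted(required - set(df.columns))}"
        )
    df = df.copy()
    df["age"] = pd.to_numeric(df["age"], errors="raise").astype(int)
    df["simd_quintile"] = pd.to_numeric(df["simd_quintile"], errors="raise").astype(int)
    if not df["sex"].isin(SEX_LEVELS).all():
        bad = sorted(set(df["sex"]) - set(SEX_LEVELS))
        raise IngestError(f"unknown sex label(s) {bad}")
    if not df["urban_rural"].isin(URBAN_RURAL_LEVELS).all():
        bad = sorted(set(df["urban_rural"]) - set(URBAN_RURAL_LEVELS))
        raise IngestError(f"unknown urban_rural label(s) {bad}")
    if not df["simd_quintile"].between(1, 5).all():
        bad = sorted(set(df.loc[~df["simd_quintile"].between(1, 5), "simd_quintile"]))
        raise IngestError(f"simd_quintile out of range 1..5: {bad}")
    if not df["care_home"].isin(["0", "1"]).all():
        raise IngestError("care_home must be 0/1")
    df["care_home"] = df["care_home"].astype(int).astype(bool)

    n_in = len(df)
    young = df["age"] < MIN_COHORT_AGE
    if young.any():
        logger.info("rejecting %d row(s) with age < %d (cohort definition)",
                    int(young.sum()), MIN_COHORT_AGE)
    no_practice = df["practice_id"].str.strip() == ""
    if no_practice.any():
        logger.info("rejecting %d row(s) with missing practice_id", int(no_practice.sum()))
    df = df.loc[~(young | no_practice)].reset_index(drop=True)
    if df["patient_id"].duplicated().any():
        raise IngestError("duplicate patient_id in patient file")
    df.attrs["n_rejected"] = n_in - len(df)
    return df


def read_dispensing(path: str | Path) -> pd.DataFrame:
    """Read dispensing records (patient_id, dispense_date, product_code).

    Dates are ISO 8601; duplicate rows are retained (distinct-class
    counting downstream neutralises them while audit counts stay exact).
    """
    df = _read_delimited(Path(path))
    required = {"patient_id", "dispense_date", "product_code"}
    if not required.issubset(df.columns):
        raise IngestError(
            f"dispensing file missing columns {sorted(required - set(df.columns))}"
        )
    df = df.copy()
    df["dispense_date"] = pd.to_datetime(
        df["dispense_date"], format="%Y-%m-%d", errors="raise"
    ).dt.date
    return df


def window_filter(
    records: pd.DataFrame, index_date: date | str, window_days: int = 84
) -> pd.DataFrame:
    """Keep records inside the exposure window ending on the index date.

    The window spans exactly ``window_days`` calendar days inclusive of
    the index date: a record is kept iff
    ``index_date - (window_days - 1) <= dispense_date <= index_date``.
    Idempotent and order-independent.
    """
    if window_days < 1:
        raise IngestError(f"window_days must be >= 1, got {window_days}")
    if isinstance(index_date, str):
        index_date = date.fromisoformat(index_date)
    start = index_date - timedelta(days=window_days - 1)
    d = records["dispense_date"]
    keep = (d >= start) & (d <= index_date)
    out = records.loc[keep].reset_index(drop=True)
    out.attrs["window"] = (start.isoformat(), index_date.isoformat())
    out.attrs["n_dropped"] = len(records) - len(out)
    return out
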