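"""CSV/JSON dialects for cohort tables and results.

The measurement table is long-format CSV with columns
``pair_id,fetus_id,zygosity,ga_weeks,trait,value``; gestational ages are
decimal weeks but the "WwDd" day notation (e.g. ``13w6d``) is also accepted
on input and parsed as weeks + days/7.  Writing uses 15 significant digits
so a write -> read round trip is lossless.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

__all__ = [
    "parse_ga",
    "read_measurements",
    "write_measurements",
    "read_covariates",
    "write_covariates",
]

VALID_TRAITS = ("AC", "HL", "FL", "HC", "EFW")

_GA_RE = re.compile(r"^\s*(\d+)w([0-6])d\s*$", re.IGNORECASE)

MEASUREMENT_COLUMNS = ["pair_id", "fetus_id", "zygosity", "ga_weeks", "trait", "value"]
COVARIATE_COLUMNS = [
    "pair_id", "fetus_id", "zygosity", "sex", "maternal_age", "pre_pregnancy_bmi",
    "smoking", "alcohol", "race", "parity", "gravidity", "employment", "education",
    "marital", "delivery_ga",
]


class TableFormatError(ValueError):
    """Raised for malformed cohort tables, listing offending line numbers."""


def parse_ga(value) -> float:
    """Parse a gestational age: decimal weeks or 'WwDd' (13w6d -> 13 + 6/7)."""
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    m = _GA_RE.match(str(value))
    if m:
        return int(m.group(1)) + int(m.group(2)) / 7.0
    try:
        return float(value)
    except ValueError as exc:
        raise TableFormatError(f"cannot parse gestational age {value!r}") from exc


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a long-format measurement CSV.

    Rejects missing columns, unknown trait names, non-positive values and
    duplicated (pair, fetus, GA, trait) keys, reporting CSV line numbers
    (header = line 1).
    """
    df = pd.read_csv(path, dtype={"pair_id": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    lines = df.index.to_numpy() + 2  # header is line 1
    df["ga_weeks"] = [parse_ga(v) for v in df["ga_weeks"]]
    bad = ~df["trait"].isin(VALID_TRAITS)
    if bad.any():
        raise TableFormatError(
            f"{path}: unknown trait names on lines {lines[bad].tolist()}"
        )
    bad = ~(df["value"] > 0)
    if bad.any():
        raise TableFormatError(
            f"{path}: non-positive values on lines {lines[bad].tolist()}"
        )
    bad = ~df["zygosity"].isin(("MZ", "DZ"))
    if bad.any():
        raise TableFormatError(
            f"{path}: zygosity must be MZ or DZ on lines {lines[bad].tolist()}"
        )
    key = ["pair_id", "fetus_id", "ga_weeks", "trait"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        raise TableFormatError(
            f"{path}: duplicated (pair, fetus, ga, trait) keys on lines {lines[dup].tolist()}"
        )
    return df[MEASUREMENT_COLUMNS]


def write_measurements(df: pd.DataFrame, path) -> None:
    df[MEASUREMENT_COLUMNS].to_csv(path, index=False, float_format="%.15g")


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"pair_id": str})
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    lines = df.index.to_numpy() + 2
    dup = df.duplicated(subset=["pair_id", "fetus_id"], keep=False)
    if dup.any():
        raise TableFormatError(
            f"{path}: duplicated (pair, fetus) rows on lines {lines[dup].tolist()}"
        )
    return df[COVARIATE_COLUMNS]


def write_covariates(df: pd.DataFrame, path) -> None:
    df[COVARIATE_COLUMNS].to_csv(path, index=False, float_format="%.15g")
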