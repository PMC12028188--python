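"""Cohort CSV loading with lenient numeric parsing and column mapping."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .synthetic import BIOCHEMICAL_VARS, VisitRecord, frame_to_records

logger = logging.getLogger(__name__)

__all__ = ["load_cohort_csv"]

REQUIRED_COLUMNS = ["patient_id", "cohort", "hcc",
                    "age_at_diagnosis", "age_at_control"] + BIOCHEMICAL_VARS

_TRUTHY = {"true", "1", "1.0", "yes", "y", "t"}
_FALSY = {"false", "0", "0.0", "no", "n", "f"}


def _parse_bool(series: pd.Series) -> pd.Series:
    def one(v):
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY:
            return False
        return np.nan
    return series.map(one)


def load_cohort_csv(path: str | Path,
                    column_map: Mapping[str, str] | None = None) -> list[VisitRecord]:
    """Read a per-visit cohort CSV into typed records.

    ``column_map`` maps canonical field names to the file's column names,
    letting real-world exports with different headers be ingested.
    Malformed numeric cells become missing values with a logged count; row
    order is preserved.  Missing required columns raise a schema error
    listing them.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        raw = raw.rename(columns=rename)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing required columns: {missing_cols}")

    df = pd.DataFrame(index=raw.index)
    df["patient_id"] = raw["patient_id"].astype(str)
    df["cohort"] = raw["cohort"].astype(str)
    hcc = _parse_bool(raw["hcc"])
    if hcc.isna().any():
        raise SchemaError("hcc column contains unparseable values")
    df["hcc"] = hcc.astype(bool)

    n_bad = 0
    numeric_cols = ["age_at_diagnosis", "age_at_control"] + [
        v for v in BIOCHEMICAL_VARS if v != "suac_detected"]
    for col in numeric_cols:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        n_bad += int((parsed.isna() & raw[col].notna()).sum())
        df[col] = parsed

    suac = _parse_bool(raw["suac_detected"])
    n_bad += int((suac.isna() & raw["suac_detected"].notna()).sum())
    df["suac_detected"] = suac.map(lambda v: float(v) if v is not np.nan and not pd.isna(v) else np.nan)

    if n_bad:
        logger.warning("load_cohort_csv: %d malformed cell(s) treated as missing", n_bad)

    ages_bad = df["age_at_diagnosis"].isna() | df["age_at_control"].isna()
    if ages_bad.any():
        raise SchemaError(
            f"{int(ages_bad.sum())} row(s) lack parseable ages; ages are required")
    return frame_to_records(df)
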