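"""Synthetic follow-up cohort generator.

Produces per-visit records for three cohorts (labelled A, B, C) with the
statistical structure the downstream analysis assumes: right-skewed
positive biomarker distributions, a latent logistic dependence of
AFP-altered status on a configurable set of covariates, patient-level HCC
status, mostly-undetectable urinary succinylacetone under treatment, and
completely-at-random missingness at per-cohort rates.

Defaults mirror the observed summary statistics of the three clinical
cohorts the pipeline was designed around: diagnosis-age medians of roughly
9 / 20 / 0.2 months, AFP medians ordered B > A > C, HCC prevalences of
2/20, 6/10 and 0/5 (C's default raised to 0 stays 0), and missingness of
3.05% / 4.62% / 7.07%.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ConfigurationError

__all__ = [
    "COHORTS",
    "BIOCHEMICAL_VARS",
    "AGE_VARS",
    "MODELED_VARS",
    "FEATURES_BIOCHEM",
    "FEATURES_WITH_AGE",
    "SyntheticConfig",
    "VisitRecord",
    "generate_cohorts",
    "records_to_frame",
    "frame_to_records",
    "write_cohort_csv",
]

COHORTS = ("A", "B", "C")

#: The 13 biochemical variables measured at each control visit.
BIOCHEMICAL_VARS = [
    "ntbc",
    "afp",
    "phe",
    "met",
    "tyr",
    "alt",
    "ast",
    "ggt",
    "prothrombin_time",
    "total_bilirubin",
    "alkaline_phosphatase",
    "glycemia",
    "suac_detected",
]

AGE_VARS = ["age_at_diagnosis", "age_at_control"]

#: Completeness is assessed over these 15 modeled variables.
MODELED_VARS = BIOCHEMICAL_VARS + AGE_VARS

#: Model features when age variables are excluded (AFP is the target).
FEATURES_BIOCHEM = [v for v in BIOCHEMICAL_VARS if v != "afp"]

#: Model features when age variables are included.
FEATURES_WITH_AGE = FEATURES_BIOCHEM + AGE_VARS

# log-normal (log-median, log-sigma) for each continuous biomarker; medians
# sit inside plausible paediatric follow-up ranges.
_BIOMARKER_PARAMS: Mapping[str, tuple[float, float]] = {
    "ntbc": (np.log(40.0), 0.50),
    "phe": (np.log(55.0), 0.35),
    "met": (np.log(30.0), 0.45),
    "tyr": (np.log(380.0), 0.35),
    "alt": (np.log(25.0), 0.50),
    "ast": (np.log(35.0), 0.45),
    "ggt": (np.log(30.0), 0.60),
    "prothrombin_time": (np.log(1.0), 0.15),
    "total_bilirubin": (np.log(0.6), 0.50),
    "alkaline_phosphatase": (np.log(250.0), 0.45),
    "glycemia": (np.log(90.0), 0.15),
}

# reference scales used to standardize covariates inside the latent
# logistic model, so effect coefficients are per-SD log-odds
_Z_REFERENCE: Mapping[str, tuple[float, float]] = {
    "alt": _BIOMARKER_PARAMS["alt"],
    "ast": _BIOMARKER_PARAMS["ast"],
    "ggt": _BIOMARKER_PARAMS["ggt"],
    "alkaline_phosphatase": _BIOMARKER_PARAMS["alkaline_phosphatase"],
    "ntbc": _BIOMARKER_PARAMS["ntbc"],
    "phe": _BIOMARKER_PARAMS["phe"],
    "met": _BIOMARKER_PARAMS["met"],
    "tyr": _BIOMARKER_PARAMS["tyr"],
    "prothrombin_time": _BIOMARKER_PARAMS["prothrombin_time"],
    "total_bilirubin": _BIOMARKER_PARAMS["total_bilirubin"],
    "glycemia": _BIOMARKER_PARAMS["glycemia"],
    "age_at_diagnosis": (np.log(9.0), 1.0),
    "age_at_control": (np.log(60.0), 0.8),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for the simulated follow-up cohorts.

    Identical config + seed yields bit-identical output.
    """

    cohort_sizes: tuple[int, int, int] = (20, 10, 5)
    visits_per_patient: tuple[int, int] = (5, 8)
    #: per-cohort (log-median, log-sigma, min, max) of diagnosis age in months
    dx_age_params: tuple[tuple[float, float, float, float], ...] = (
        (np.log(9.0), 0.70, 1.0, 63.0),
        (np.log(20.0), 0.45, 6.0, 48.0),
        (np.log(0.25), 0.15, 0.2, 0.33),
    )
    #: per-variable log-odds weight (per SD) in the latent AFP-status model
    effect_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {
            "alt": 1.2,
            "alkaline_phosphatase": 0.9,
            "age_at_diagnosis": 0.6,
            "age_at_control": 0.3,
        }
    )
    cohort_intercepts: tuple[float, float, float] = (0.4, 1.0, 1.0)
    hcc_prevalence: tuple[float, float, float] = (0.10, 0.60, 0.0)
    missingness_rates: tuple[float, float, float] = (0.0305, 0.0462, 0.0707)
    suac_detect_prob: float = 0.05
    #: multiplicative ALT elevation and extra log-odds for HCC patients
    hcc_alt_multiplier: float = 1.8
    hcc_logit_boost: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if len(self.cohort_sizes) != 3 or any(int(n) < 1 for n in self.cohort_sizes):
            raise ConfigurationError("cohort_sizes: three integers >= 1 required")
        lo, hi = self.visits_per_patient
        if lo < 1 or hi < lo:
            raise ConfigurationError("visits_per_patient: need 1 <= low <= high")
        if len(self.dx_age_params) != 3:
            raise ConfigurationError("dx_age_params: one tuple per cohort required")
        for p in self.hcc_prevalence:
            if not 0.0 <= p < 1.0 and p != 1.0:
                raise ConfigurationError("hcc_prevalence: values must lie in [0, 1]")
        for r in self.missingness_rates:
            if not 0.0 <= r < 1.0:
                raise ConfigurationError("missingness_rates: values must lie in [0, 1)")
        if not 0.0 <= self.suac_detect_prob <= 1.0:
            raise ConfigurationError("suac_detect_prob: must lie in [0, 1]")
        for name, coeff in self.effect_coefficients.items():
            if name not in _Z_REFERENCE:
                raise ConfigurationError(f"effect_coefficients: unknown variable '{name}'")
            float(coeff)
        if self.hcc_alt_multiplier <= 0:
            raise ConfigurationError("hcc_alt_multiplier: must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_coefficients"] = dict(self.effect_coefficients)
        return d


@dataclass
class VisitRecord:
    """One outpatient control visit; ``None`` marks a missing measurement."""

    patient_id: str
    cohort: str
    hcc: bool
    age_at_diagnosis: float
    age_at_control: float
    ntbc: Optional[float] = None
    afp: Optional[float] = None
    phe: Optional[float] = None
    met: Optional[float] = None
    tyr: Optional[float] = None
    alt: Optional[float] = None
    ast: Optional[float] = None
    ggt: Optional[float] = None
    prothrombin_time: Optional[float] = None
    total_bilirubin: Optional[float] = None
    alkaline_phosphatase: Optional[float] = None
    glycemia: Optional[float] = None
    suac_detected: Optional[bool] = None


def _zscore(name: str, value: np.ndarray) -> np.ndarray:
    mu, sigma = _Z_REFERENCE[name]
    return (np.log(value) - mu) / sigma


def generate_cohorts(config: SyntheticConfig) -> list[VisitRecord]:
    """Generate visit records for all three cohorts.

    Covariates are drawn from right-skewed log-normal distributions; the
    latent AFP-altered status follows a logistic model on the configured
    covariates; the AFP value is then drawn conditionally below/above
    5 ng/mL with a location that increases with the linear predictor (so a
    planted effect also shows up as a monotone covariate-AFP association).
    Missingness is applied completely at random to the biochemical columns
    only, never to identifiers, ages, or HCC status.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[VisitRecord] = []

    for ci, cohort in enumerate(COHORTS):
        n_patients = int(config.cohort_sizes[ci])
        n_hcc = int(round(config.hcc_prevalence[ci] * n_patients))
        hcc_flags = np.zeros(n_patients, dtype=bool)
        hcc_flags[rng.permutation(n_patients)[:n_hcc]] = True
        mu_dx, sd_dx, lo_dx, hi_dx = config.dx_age_params[ci]
        intercept = config.cohort_intercepts[ci]

        cohort_rows: list[VisitRecord] = []
        for pi in range(n_patients):
            pid = f"{cohort}{pi + 1:03d}"
            hcc = bool(hcc_flags[pi])
            dx_age = float(np.clip(rng.lognormal(mu_dx, sd_dx), lo_dx, hi_dx))
            n_visits = int(rng.integers(config.visits_per_patient[0],
                                        config.visits_per_patient[1] + 1))
            for v in range(n_visits):
                age = dx_age + 3.0 * (v + 1)  # quarterly controls
                vals = {
                    name: float(rng.lognormal(mu, sd))
                    for name, (mu, sd) in _BIOMARKER_PARAMS.items()
                }
                if hcc:
                    vals["alt"] *= config.hcc_alt_multiplier
                lin = intercept + (config.hcc_logit_boost if hcc else 0.0)
                for name, coeff in config.effect_coefficients.items():
                    if name == "age_at_diagnosis":
                        z = _zscore(name, np.array(dx_age))
                    elif name == "age_at_control":
                        z = _zscore(name, np.array(age))
                    else:
                        z = _zscore(name, np.array(vals[name]))
                    lin += float(coeff) * float(z)
                altered = rng.random() < expit(lin)
                if altered:
                    afp = 5.0 + float(
                        np.exp(rng.normal(1.2 + 0.5 * lin + (0.5 if hcc else 0.0), 0.8))
                    )
                else:
                    afp = 5.0 * float(expit(rng.normal(0.3 * lin - 0.3, 0.6)))
                suac = bool(rng.random() < config.suac_detect_prob)
                cohort_rows.append(
                    VisitRecord(
                        patient_id=pid,
                        cohort=cohort,
                        hcc=hcc,
                        age_at_diagnosis=dx_age,
                        age_at_control=age,
                        afp=afp,
                        suac_detected=suac,
                        **{k: vals[k] for k in _BIOMARKER_PARAMS},
                    )
                )

        rate = config.missingness_rates[ci]
        if rate > 0.0:
            mask = rng.random((len(cohort_rows), len(BIOCHEMICAL_VARS))) < rate
            for r, row in enumerate(cohort_rows):
                for j, name in enumerate(BIOCHEMICAL_VARS):
                    if mask[r, j]:
                        setattr(row, name, None)
        records.extend(cohort_rows)

    return records


_CSV_COLUMNS = ["patient_id", "cohort", "hcc"] + AGE_VARS + BIOCHEMICAL_VARS


def records_to_frame(records: Sequence[VisitRecord]) -> pd.DataFrame:
    """Tabulate records; missing values become NaN, suac becomes 0/1 float."""
    rows = []
    for rec in records:
        row = {c: getattr(rec, c) for c in _CSV_COLUMNS}
        if row["suac_detected"] is not None:
            row["suac_detected"] = float(row["suac_detected"])
        rows.append(row)
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df["hcc"] = df["hcc"].astype(bool)
    return df


def frame_to_records(df: pd.DataFrame) -> list[VisitRecord]:
    records = []
    for _, row in df.iterrows():
        kwargs = {"patient_id": str(row["patient_id"]),
                  "cohort": str(row["cohort"]),
                  "hcc": bool(row["hcc"]),
                  "age_at_diagnosis": float(row["age_at_diagnosis"]),
                  "age_at_control": float(row["age_at_control"])}
        for name in BIOCHEMICAL_VARS:
            v = row[name]
            if pd.isna(v):
                kwargs[name] = None
            elif name == "suac_detected":
                kwargs[name] = bool(float(v))
            else:
                kwargs[name] = float(v)
        records.append(VisitRecord(**kwargs))
    return records


def write_cohort_csv(records: Sequence[VisitRecord], path: str | Path,
                     config: SyntheticConfig | None = None) -> Path:
    """Write one row per visit (empty cell = missing) plus a JSON sidecar
    recording the generating config when one is supplied."""
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    return path
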