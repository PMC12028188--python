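"""Record filtering, target binarization, chained-equations imputation,
and 2-D embedding of the completed feature matrix."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .exceptions import ConfigurationError, DegenerateInputError, InsufficientDataError
from .synthetic import (
    FEATURES_BIOCHEM,
    FEATURES_WITH_AGE,
    MODELED_VARS,
    VisitRecord,
    records_to_frame,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisDataset",
    "filter_records",
    "binarize_afp",
    "impute_missing",
    "embed_2d",
    "build_dataset",
]


@dataclass
class AnalysisDataset:
    """Completed records-by-features matrix plus per-record metadata."""

    feature_matrix: np.ndarray
    feature_names: list[str]
    target: np.ndarray
    cohort_labels: np.ndarray
    patient_ids: np.ndarray
    hcc_flags: np.ndarray

    def __post_init__(self):
        if np.isnan(self.feature_matrix).any():
            raise ValueError("feature_matrix must contain no missing entries")

    @property
    def n_records(self) -> int:
        return self.feature_matrix.shape[0]

    def subset(self, idx: np.ndarray) -> "AnalysisDataset":
        return AnalysisDataset(
            self.feature_matrix[idx],
            list(self.feature_names),
            self.target[idx],
            self.cohort_labels[idx],
            self.patient_ids[idx],
            self.hcc_flags[idx],
        )


def filter_records(records: Sequence[VisitRecord],
                   min_completeness: float = 0.7) -> list[VisitRecord]:
    """Keep records with >= ``min_completeness`` of the 15 modeled variables
    present and with both AFP and SUAC measured.

    Empty input yields empty output; removing every record logs a warning.
    """
    if not 0.0 < min_completeness <= 1.0:
        raise ConfigurationError("min_completeness: must lie in (0, 1]")
    kept = []
    for rec in records:
        present = sum(getattr(rec, v) is not None for v in MODELED_VARS)
        if (present / len(MODELED_VARS) >= min_completeness
                and rec.afp is not None and rec.suac_detected is not None):
            kept.append(rec)
    if records and not kept:
        logger.warning("filter_records removed all %d records", len(records))
    return kept


def binarize_afp(afp: Optional[float], threshold: float = 5.0) -> int:
    """1 iff AFP strictly exceeds the threshold; exact equality is normal."""
    if afp is None or (isinstance(afp, float) and np.isnan(afp)):
        raise DegenerateInputError("AFP is missing; filtering should have removed it")
    if afp <= 0:
        raise DegenerateInputError(f"AFP must be positive, got {afp!r}")
    return int(afp > threshold)


def impute_missing(matrix: pd.DataFrame | np.ndarray, seed: int = 0,
                   max_iter: int = 10, tol: float = 1e-3):
    """Fill missing cells by round-robin regression of each incomplete
    column on the others (chained equations); observed cells are returned
    bit-identical.  Deterministic under a fixed seed."""
    is_frame = isinstance(matrix, pd.DataFrame)
    values = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    names = list(matrix.columns) if is_frame else [str(i) for i in range(values.shape[1])]

    observed = ~np.isnan(values)
    for j, name in enumerate(names):
        n_obs = int(observed[:, j].sum())
        if n_obs == 0:
            raise DegenerateInputError(f"column '{name}' is fully missing")
        if n_obs < 2:
            raise InsufficientDataError(f"column '{name}' has fewer than 2 observed values")

    if observed.all():
        return matrix.copy() if is_frame else values.copy()

    imputer = IterativeImputer(max_iter=max_iter, tol=tol, random_state=seed,
                               sample_posterior=False, keep_empty_features=True)
    completed = imputer.fit_transform(values)
    # guarantee observed cells are untouched regardless of backend details
    completed[observed] = values[observed]
    if is_frame:
        return pd.DataFrame(completed, index=matrix.index, columns=names)
    return completed


def embed_2d(matrix: np.ndarray, seed: int = 0, n_neighbors: int = 15,
             min_dist: float = 0.1) -> np.ndarray:
    """Standardized 2-D UMAP embedding, for cohort-overlap visualization only.

    Deterministic under a fixed seed; never fed to downstream modelling.
    """
    matrix = np.asarray(matrix, dtype=float)
    if np.isnan(matrix).any():
        raise DegenerateInputError("embedding requires a completed matrix")
    n = matrix.shape[0]
    if n < 10:
        raise InsufficientDataError(f"embedding needs >= 10 records, got {n}")
    if n <= n_neighbors:
        raise InsufficientDataError(
            f"{n} records <= n_neighbors={n_neighbors}; pass a smaller n_neighbors"
        )
    import umap  # deferred: heavy import

    std = matrix.std(axis=0)
    std[std == 0] = 1.0
    scaled = (matrix - matrix.mean(axis=0)) / std
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    return np.asarray(reducer.fit_transform(scaled), dtype=float)


def build_dataset(records: Sequence[VisitRecord], include_age: bool = False,
                  afp_threshold: float = 5.0, min_completeness: float = 0.7,
                  seed: int = 0) -> AnalysisDataset:
    """Filter records, binarize the AFP target, and impute the features.

    SUAC enters as a 0/1 column and is excluded from the imputation
    regressions (records with missing SUAC were already filtered out).
    """
    kept = filter_records(records, min_completeness)
    if not kept:
        raise InsufficientDataError("no records survive filtering")
    df = records_to_frame(kept)
    target = np.array([binarize_afp(a, afp_threshold) for a in df["afp"]], dtype=int)

    feature_names = list(FEATURES_WITH_AGE if include_age else FEATURES_BIOCHEM)
    continuous = [f for f in feature_names if f != "suac_detected"]
    completed = impute_missing(df[continuous], seed=seed)
    matrix = pd.DataFrame(completed, columns=continuous, index=df.index)
    matrix["suac_detected"] = df["suac_detected"].astype(float)
    matrix = matrix[feature_names]

    logger.info("build_dataset: %d/%d records kept, %d features (include_age=%s)",
                len(kept), len(records), len(feature_names), include_age)
    return AnalysisDataset(
        feature_matrix=matrix.to_numpy(dtype=float),
        feature_names=feature_names,
        target=target,
        cohort_labels=df["cohort"].to_numpy(dtype=object),
        patient_ids=df["patient_id"].to_numpy(dtype=object),
        hcc_flags=df["hcc"].to_numpy(dtype=bool),
    )
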