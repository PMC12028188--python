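"""Logistic-regression model of altered AFP with leave-one-variable-out
ablation over the consensus candidate variables."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .exceptions import DegenerateInputError, SplitError
from .multimodel import auroc

logger = logging.getLogger(__name__)

__all__ = ["ThreeWaySplit", "AblationReport", "make_three_way_split",
           "fit_logistic", "ablation_scan"]

_PARTITIONS = ("training", "validation", "testing")


@dataclass(frozen=True)
class ThreeWaySplit:
    train_indices: np.ndarray
    validation_indices: np.ndarray
    test_indices: np.ndarray


@dataclass
class AblationReport:
    """One row per model variant: the complete model plus one per omitted
    variable; columns are per-partition AUROCs."""

    rows: pd.DataFrame
    worst_omission: str


def make_three_way_split(labels, fractions=(0.6, 0.2, 0.2), seed: int = 0,
                         max_attempts: int = 100) -> ThreeWaySplit:
    """Random train/validation/test partition redrawn until every part
    contains both classes."""
    y = np.asarray(labels).astype(int)
    n = len(y)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        tr = perm[:n_train]
        va = perm[n_train:n_train + n_val]
        te = perm[n_train + n_val:]
        if all(len(np.unique(y[part])) == 2 for part in (tr, va, te)):
            return ThreeWaySplit(np.sort(tr), np.sort(va), np.sort(te))
    raise SplitError(f"no valid three-way split after {max_attempts} attempts")


def fit_logistic(features: np.ndarray, labels, split: ThreeWaySplit,
                 seed: int = 0) -> dict[str, float]:
    """Maximum-likelihood logistic fit on the training part only; AUROC
    reported on all three partitions.

    Perfect separation (detected as non-convergence or exploding
    coefficients) triggers a ridge-stabilized refit with a logged warning.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    tr = split.train_indices
    if len(np.unique(y[tr])) < 2:
        raise DegenerateInputError("training partition is single-class")

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(penalty=None, max_iter=500, random_state=seed)
        model.fit(X[tr], y[tr])
        unstable = (model.n_iter_[0] >= 500
                    or np.abs(model.coef_).max() > 1e3)
        if unstable:
            logger.warning("fit_logistic: separation suspected, refitting with ridge")
            model = LogisticRegression(penalty="l2", C=1.0, max_iter=500,
                                       random_state=seed)
            model.fit(X[tr], y[tr])

    out = {}
    for name, idx in zip(_PARTITIONS, (split.train_indices,
                                       split.validation_indices,
                                       split.test_indices)):
        out[name] = auroc(model.decision_function(X[idx]), y[idx])
    out["coefficients"] = model.coef_[0].copy()
    return out


def ablation_scan(features: pd.DataFrame, labels, split: ThreeWaySplit,
                  seed: int = 0) -> AblationReport:
    """Fit the complete model and each leave-one-variable-out variant on
    identical partitions; flag the omission causing the largest test-AUROC
    drop."""
    if not isinstance(features, pd.DataFrame):
        raise TypeError("features must be a DataFrame with named columns")
    variables = list(features.columns)
    y = np.asarray(labels).astype(int)

    rows = []
    for omitted in variables:
        keep = [v for v in variables if v != omitted]
        res = fit_logistic(features[keep].to_numpy(), y, split, seed)
        rows.append({"omitted_variable": omitted,
                     **{p: res[p] for p in _PARTITIONS}})
    complete = fit_logistic(features.to_numpy(), y, split, seed)
    rows.append({"omitted_variable": None,
                 **{p: complete[p] for p in _PARTITIONS}})

    report = pd.DataFrame(rows)
    ablated = report[report["omitted_variable"].notna()]
    worst = ablated.loc[ablated["testing"].idxmin(), "omitted_variable"]
    return AblationReport(rows=report, worst_omission=str(worst))
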