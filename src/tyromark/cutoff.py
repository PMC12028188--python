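"""Per-patient aggregation, ROC-derived biomarker threshold for HCC
discrimination, and the combined AFP+ALT screening table."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, SchemaError
from .multimodel import auroc
from .synthetic import VisitRecord, records_to_frame

logger = logging.getLogger(__name__)

__all__ = ["CutoffResult", "patient_means", "roc_cutoff", "screening_table"]


@dataclass
class CutoffResult:
    threshold: float
    sensitivity: float
    specificity: float
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("threshold", "sensitivity", "specificity", "auc",
                 "ci_low", "ci_high", "n_pos", "n_neg")}


def patient_means(records: Sequence[VisitRecord], variable: str) -> pd.DataFrame:
    """Arithmetic mean of each patient's non-missing values of ``variable``,
    with the patient-level HCC label carried through.

    Patients with no observed value are excluded with a warning.
    """
    df = records_to_frame(records)
    if variable not in df.columns:
        raise KeyError(f"unknown variable '{variable}'")
    out = (df.groupby("patient_id", sort=True)
             .agg(mean_value=(variable, "mean"), hcc=("hcc", "first"))
             .reset_index())
    dropped = out["mean_value"].isna()
    if dropped.any():
        logger.warning("patient_means: %d patient(s) had no observed %s",
                       int(dropped.sum()), variable)
    return out[~dropped].reset_index(drop=True)


def _sens_spec(values: np.ndarray, labels: np.ndarray, thr: float):
    pos, neg = labels == 1, labels == 0
    sens = float((values[pos] > thr).mean())
    spec = float((values[neg] <= thr).mean())
    return sens, spec


def roc_cutoff(values: Sequence[float], labels: Sequence[bool],
               n_boot: int = 2000, seed: int = 0) -> CutoffResult:
    """Youden-optimal threshold over midpoints between consecutive sorted
    unique values, with a stratified patient-level percentile bootstrap for
    the AUC 95% CI.

    A patient is called positive when the value strictly exceeds the
    threshold.  Ties in Youden's J resolve to the lowest threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if v.shape != y.shape:
        raise SchemaError("values and labels must be aligned")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise DegenerateInputError("need >= 2 patients in each class")

    auc = auroc(v, y)
    uniq = np.unique(v)
    if len(uniq) < 2:
        raise DegenerateInputError("all values identical; no threshold exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_thr, best_j, best_sens, best_spec = None, -np.inf, 0.0, 0.0
    for thr in candidates:  # ascending, so strict improvement keeps lowest tie
        sens, spec = _sens_spec(v, y, thr)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_thr, best_j, best_sens, best_spec = float(thr), j, sens, spec

    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.where(y == 1)[0], np.where(y == 0)[0]
    boot_aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos_idx, size=n_pos, replace=True)
        bn = rng.choice(neg_idx, size=n_neg, replace=True)
        idx = np.concatenate([bp, bn])
        boot_aucs[b] = auroc(v[idx], y[idx])
    ci_low, ci_high = np.percentile(boot_aucs, [2.5, 97.5])

    return CutoffResult(threshold=best_thr, sensitivity=best_sens,
                        specificity=best_spec, auc=auc,
                        ci_low=float(ci_low), ci_high=float(ci_high),
                        n_pos=n_pos, n_neg=n_neg)


def screening_table(afp_means: Sequence[float], alt_means: Sequence[float],
                    labels: Sequence[bool], afp_cuts: Sequence[float] = (5.0, 10.0),
                    alt_cut: float = 29.0) -> pd.DataFrame:
    """False-positive % (among non-HCC) and sensitivity % (among HCC) for
    AFP-alone and combined AFP+ALT flagging rules.

    A patient is flagged AFP-alone when mean AFP strictly exceeds the cut,
    and by the combined rule when additionally mean ALT exceeds the ALT
    cut; the combined flagged set is therefore a subset of the AFP-alone
    set at the same cut-off.
    """
    afp = np.asarray(afp_means, dtype=float)
    alt = np.asarray(alt_means, dtype=float)
    y = np.asarray(labels).astype(int)
    if not (afp.shape == alt.shape == y.shape):
        raise SchemaError("afp_means, alt_means and labels must be aligned")
    pos, neg = y == 1, y == 0

    def pct(mask, group):
        denom = int(group.sum())
        return float("nan") if denom == 0 else 100.0 * float(mask[group].sum()) / denom

    rows = []
    for cut in afp_cuts:
        afp_flag = afp > cut
        both_flag = afp_flag & (alt > alt_cut)
        rows.append({"rule": f"AFP>{cut:g}", "afp_cut": float(cut),
                     "alt_cut": None,
                     "false_positive_pct": pct(afp_flag, neg),
                     "sensitivity_pct": pct(afp_flag, pos)})
        rows.append({"rule": f"AFP>{cut:g}+ALT>{alt_cut:g}", "afp_cut": float(cut),
                     "alt_cut": float(alt_cut),
                     "false_positive_pct": pct(both_flag, neg),
                     "sensitivity_pct": pct(both_flag, pos)})
    return pd.DataFrame(rows)
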