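"""Corrected-importance computation, per-cohort variable rankings, and
cross-cohort hierarchical consensus clustering.

The corrected importance of a variable in a cohort is the mean, over
retained model rounds, of that round's mean-|SHAP| for the variable
multiplied by the round's AUROC on the cohort's test set.  Clustering
operates on the raw (unstandardized) variables-by-cohorts matrix so that
"highly important" forms a high-valued cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .exceptions import EmptyResultError, InsufficientDataError
from .multimodel import ModelRound

logger = logging.getLogger(__name__)

__all__ = [
    "ImportanceTable",
    "ClusterResult",
    "corrected_importance",
    "build_importance_table",
    "rank_variables",
    "compare_importance_distributions",
    "consensus_cluster",
    "linkage_to_newick",
]


@dataclass
class ImportanceTable:
    """Variables-by-cohorts matrix of corrected importance."""

    values: pd.DataFrame  # index = variables, columns = cohorts
    n_models: dict[str, int]

    @property
    def variables(self) -> list[str]:
        return list(self.values.index)

    @property
    def cohorts(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    flat_labels: dict[str, int]
    top_cluster: list[str]
    newick: str
    cohort_linkage: np.ndarray | None = None


def _usable(rounds: Sequence[ModelRound], cohort: str) -> list[ModelRound]:
    return [r for r in rounds
            if cohort in r.auroc_by_testset
            and np.isfinite(r.auroc_by_testset[cohort])]


def corrected_importance(rounds: Sequence[ModelRound], cohort: str,
                         feature_names: Sequence[str]) -> pd.Series:
    """Per-variable mean over retained rounds of SHAP(v) * AUROC(cohort)."""
    usable = _usable(rounds, cohort)
    if not usable:
        raise EmptyResultError(f"no retained rounds with results for '{cohort}'")
    acc = np.zeros(len(feature_names))
    for r in usable:
        acc += r.shap_by_testset[cohort] * r.auroc_by_testset[cohort]
    return pd.Series(acc / len(usable), index=list(feature_names), name=cohort)


def build_importance_table(rounds: Sequence[ModelRound], cohorts: Sequence[str],
                           feature_names: Sequence[str]) -> ImportanceTable:
    cols = {c: corrected_importance(rounds, c, feature_names) for c in cohorts}
    values = pd.DataFrame(cols)[list(cohorts)]
    n_models = {c: len(_usable(rounds, c)) for c in cohorts}
    return ImportanceTable(values=values, n_models=n_models)


def rank_variables(table: ImportanceTable, cohort: str) -> pd.DataFrame:
    """Descending ranking of corrected importance for one cohort; ties are
    broken alphabetically and flagged."""
    if cohort not in table.cohorts:
        raise KeyError(f"cohort '{cohort}' not in table {table.cohorts}")
    s = table.values[cohort]
    out = (s.rename("corrected_importance").reset_index()
            .rename(columns={"index": "variable"}))
    out = out.sort_values(["corrected_importance", "variable"],
                          ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    dup = s.duplicated(keep=False)
    out["tied"] = out["variable"].map(dict(zip(s.index, dup))).astype(bool)
    return out.reset_index(drop=True)


def compare_importance_distributions(rounds: Sequence[ModelRound], cohort: str,
                                     feature_names: Sequence[str]) -> pd.DataFrame:
    """Pairwise Mann-Whitney tests between the per-model corrected-importance
    samples of every variable pair, Bonferroni-adjusted.  Symmetric."""
    usable = _usable(rounds, cohort)
    if len(usable) < 2:
        raise InsufficientDataError("need >= 2 retained rounds for a distribution")
    samples = {
        v: np.array([r.shap_by_testset[cohort][i] * r.auroc_by_testset[cohort]
                     for r in usable])
        for i, v in enumerate(feature_names)
    }
    k = len(feature_names)
    n_pairs = k * (k - 1) // 2
    p = pd.DataFrame(np.ones((k, k)), index=list(feature_names),
                     columns=list(feature_names))
    for i, a in enumerate(feature_names):
        for b in list(feature_names)[i + 1:]:
            if np.array_equal(samples[a], samples[b]):
                praw = 1.0
            else:
                praw = float(stats.mannwhitneyu(samples[a], samples[b],
                                                alternative="two-sided").pvalue)
            padj = min(1.0, praw * n_pairs)
            p.loc[a, b] = p.loc[b, a] = padj
    return p


def consensus_cluster(table: ImportanceTable, n_clusters: int = 2,
                      method: str = "average", metric: str = "euclidean",
                      cluster_cohorts: bool = False) -> ClusterResult:
    """Agglomerative clustering of variables on their cohort-profile
    vectors; the top cluster is the flat cluster with the greatest mean
    corrected importance."""
    values = table.values
    if len(table.variables) < 2 or len(table.cohorts) < 2:
        raise InsufficientDataError("need >= 2 variables and >= 2 cohorts")
    mat = values.to_numpy(dtype=float)
    if np.allclose(mat, 0.0):
        logger.warning("consensus_cluster: all-zero table, single-cluster result")
        n_clusters = 1
    Z = hierarchy.linkage(pdist(mat, metric=metric), method=method)
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = dict(zip(table.variables, map(int, flat)))
    means = {c: mat[flat == c].mean() for c in np.unique(flat)}
    top_id = max(sorted(means), key=lambda c: means[c])
    top = [v for v, c in labels.items() if c == top_id]
    newick = linkage_to_newick(Z, table.variables)
    cohort_Z = None
    if cluster_cohorts:
        cohort_Z = hierarchy.linkage(pdist(mat.T, metric=metric), method=method)
    return ClusterResult(linkage=Z, flat_labels=labels, top_cluster=top,
                         newick=newick, cohort_linkage=cohort_Z)


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string (branch lengths =
    merge-height differences)."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
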