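"""Multi-round gradient-boosted-tree training with randomized
hyperparameters, per-cohort test evaluation, and Shapley importances.

Each round draws a fresh stratified 70:30 partition of the training
cohort, samples hyperparameters from the configured space, fits a
gradient-boosted tree classifier, and evaluates AUROC plus per-feature
mean-|SHAP| on the held-out internal test set and on every external
cohort.  Rounds whose internal-test AUROC exceeds the retention threshold
feed the consensus ranking.

The model backend is scikit-learn's ``GradientBoostingClassifier``; the
L1/L2 regularization dimensions of the sampling space act through
cost-complexity pruning (``ccp_alpha``) and the minimum impurity decrease
gate, the closest complexity controls the backend exposes.  The
cross-validation-folds dimension sets the internal validation fraction
used for early stopping; reported AUROCs always come from held-out data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier

from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    SchemaError,
    SplitError,
)
from .preprocess import AnalysisDataset
from .treeshap import mean_abs_shap

logger = logging.getLogger(__name__)

__all__ = [
    "HyperParams",
    "HyperSpace",
    "SplitPlan",
    "ModelRound",
    "MultiModelResult",
    "auroc",
    "make_split",
    "sample_hyperparams",
    "train_round",
    "run_multimodel",
]

INTERNAL = "internal"


@dataclass(frozen=True)
class HyperParams:
    tree_depth: int
    learning_rate: float
    subsample_fraction: float
    l2_penalty: float
    l1_penalty: float
    positive_class_weight: float
    cv_folds: int


@dataclass(frozen=True)
class HyperSpace:
    """Sampling ranges, one (low, high) pair per hyperparameter dimension.

    ``learning_rate`` and both penalties are drawn log-uniformly; depths
    and folds are uniform integers (inclusive); the rest are uniform.
    """

    tree_depth: tuple[int, int] = (2, 8)
    learning_rate: tuple[float, float] = (0.01, 0.3)
    subsample_fraction: tuple[float, float] = (0.5, 1.0)
    l2_penalty: tuple[float, float] = (1e-8, 1e-2)
    l1_penalty: tuple[float, float] = (1e-8, 1e-3)
    positive_class_weight: tuple[float, float] = (0.5, 4.0)
    cv_folds: tuple[int, int] = (3, 10)

    def validate(self) -> None:
        for name in self.__dataclass_fields__:
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ConfigurationError(f"{name}: inverted range ({lo}, {hi})")
            if name in ("learning_rate", "l2_penalty", "l1_penalty") and lo <= 0:
                raise ConfigurationError(f"{name}: log-uniform range must be positive")


@dataclass(frozen=True)
class SplitPlan:
    train_indices: np.ndarray
    test_indices: np.ndarray
    ratio: float = 0.7


@dataclass
class ModelRound:
    round_id: int
    hyperparams: HyperParams
    #: test-set name -> AUROC (NaN where the test set is single-class)
    auroc_by_testset: dict[str, float]
    #: test-set name -> per-feature mean-|SHAP| vector
    shap_by_testset: dict[str, np.ndarray]
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "round_id": self.round_id,
            "hyperparams": asdict(self.hyperparams),
            "auroc_by_testset": self.auroc_by_testset,
            "shap_by_testset": {k: list(map(float, v))
                                for k, v in self.shap_by_testset.items()},
            "seed": self.seed,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "ModelRound":
        d = json.loads(line)
        return cls(
            round_id=d["round_id"],
            hyperparams=HyperParams(**d["hyperparams"]),
            auroc_by_testset={k: float(v) for k, v in d["auroc_by_testset"].items()},
            shap_by_testset={k: np.asarray(v, dtype=float)
                             for k, v in d["shap_by_testset"].items()},
            seed=d["seed"],
        )


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic:
    P(score+ > score-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("AUROC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def make_split(labels: Sequence[int], ratio: float = 0.7,
               rng: np.random.Generator | None = None,
               groups: Optional[Sequence] = None,
               max_attempts: int = 100) -> SplitPlan:
    """Fresh randomized partition with ``round(ratio*n)`` training records,
    redrawn until both classes appear on both sides.

    With ``groups`` given (patient ids), whole groups are assigned to one
    side so no patient straddles the split; the train size is then the
    closest achievable to the ratio.
    """
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(labels).astype(int)
    n = len(y)
    if n < 10:
        raise SplitError(f"need >= 10 records to split, got {n}")
    if len(np.unique(y)) < 2:
        raise SplitError("both target classes must be present")
    n_train = int(round(ratio * n))

    for _ in range(max_attempts):
        if groups is None:
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
        else:
            garr = np.asarray(groups)
            uniq = rng.permutation(np.unique(garr))
            take, count = [], 0
            for g in uniq:
                size = int((garr == g).sum())
                # never exhaust the test side; stop once the quota is met
                if count >= n_train or count + size >= n:
                    break
                take.append(g)
                count += size
            mask = np.isin(garr, take)
            tr, te = np.where(mask)[0], np.where(~mask)[0]
        if (len(tr) and len(te)
                and len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2):
            return SplitPlan(train_indices=np.sort(tr),
                             test_indices=np.sort(te), ratio=ratio)
    raise SplitError(f"no valid split after {max_attempts} attempts")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return float(lo)
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_hyperparams(rng: np.random.Generator,
                       space: HyperSpace | None = None) -> HyperParams:
    """Independent draw within each dimension of the space."""
    space = space or HyperSpace()
    space.validate()
    return HyperParams(
        tree_depth=int(rng.integers(space.tree_depth[0], space.tree_depth[1] + 1)),
        learning_rate=_log_uniform(rng, *space.learning_rate),
        subsample_fraction=float(rng.uniform(*space.subsample_fraction)),
        l2_penalty=_log_uniform(rng, *space.l2_penalty),
        l1_penalty=_log_uniform(rng, *space.l1_penalty),
        positive_class_weight=float(rng.uniform(*space.positive_class_weight)),
        cv_folds=int(rng.integers(space.cv_folds[0], space.cv_folds[1] + 1)),
    )


def train_round(dataset: AnalysisDataset, split: SplitPlan,
                external: Mapping[str, AnalysisDataset],
                hp: HyperParams, seed: int, round_id: int = 0,
                n_estimators: int = 50,
                use_early_stopping: bool = False) -> ModelRound:
    """Fit one boosted-tree classifier on the train side and score AUROC
    plus mean-|SHAP| on the internal test side and each external cohort.

    External cohorts must share the dataset's feature names and order.
    Test records are never seen during fitting.  Deterministic for a fixed
    seed and inputs.
    """
    for name, ext in external.items():
        if list(ext.feature_names) != list(dataset.feature_names):
            raise SchemaError(
                f"external cohort '{name}' feature mismatch: "
                f"{list(ext.feature_names)} vs {list(dataset.feature_names)}"
            )
    X, y = dataset.feature_matrix, dataset.target
    tr, te = split.train_indices, split.test_indices
    weights = np.where(y[tr] == 1, hp.positive_class_weight, 1.0)

    kwargs = dict(
        n_estimators=n_estimators,
        max_depth=hp.tree_depth,
        learning_rate=hp.learning_rate,
        subsample=hp.subsample_fraction,
        ccp_alpha=hp.l2_penalty,
        min_impurity_decrease=hp.l1_penalty,
        random_state=seed,
    )
    if use_early_stopping:
        kwargs.update(validation_fraction=1.0 / hp.cv_folds, n_iter_no_change=10)
    model = GradientBoostingClassifier(**kwargs)
    model.fit(X[tr], y[tr], sample_weight=weights)

    aucs: dict[str, float] = {}
    shaps: dict[str, np.ndarray] = {}

    def _evaluate(name: str, Xe: np.ndarray, ye: np.ndarray) -> None:
        scores = model.decision_function(Xe)
        if len(np.unique(ye)) < 2:
            aucs[name] = float("nan")
        else:
            aucs[name] = auroc(scores, ye)
        shaps[name] = mean_abs_shap(model, Xe)

    _evaluate(INTERNAL, X[te], y[te])
    for name, ext in external.items():
        _evaluate(name, ext.feature_matrix, ext.target)

    return ModelRound(round_id=round_id, hyperparams=hp,
                      auroc_by_testset=aucs, shap_by_testset=shaps, seed=seed)


@dataclass
class MultiModelResult:
    """All trained rounds plus the retained subset passing the AUROC filter."""

    all_rounds: list[ModelRound]
    auc_threshold: float
    feature_names: list[str]
    master_seed: int

    @property
    def retained(self) -> list[ModelRound]:
        return [r for r in self.all_rounds
                if r.auroc_by_testset[INTERNAL] > self.auc_threshold]

    @property
    def retention_fraction(self) -> float:
        if not self.all_rounds:
            return 0.0
        return len(self.retained) / len(self.all_rounds)

    @property
    def status(self) -> str:
        return "ok" if self.retained else "empty"

    def refiltered(self, auc_threshold: float) -> "MultiModelResult":
        return MultiModelResult(self.all_rounds, auc_threshold,
                                self.feature_names, self.master_seed)

    def write_jsonl(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            for r in self.retained:
                fh.write(r.to_json() + "\n")
        return path


def run_multimodel(dataset: AnalysisDataset,
                   external: Mapping[str, AnalysisDataset],
                   n_rounds: int = 5000,
                   auc_threshold: float = 0.7,
                   space: HyperSpace | None = None,
                   master_seed: int = 0,
                   ratio: float = 0.7,
                   n_estimators: int = 50,
                   grouped: bool = False,
                   bootstrap: bool = False,
                   use_early_stopping: bool = False) -> MultiModelResult:
    """Execute ``n_rounds`` of (split -> sample hyperparameters -> train),
    retaining rounds whose internal-test AUROC strictly exceeds the
    threshold.

    Round seeds derive deterministically from ``master_seed``, so the full
    run is bit-reproducible.  ``bootstrap=True`` additionally resamples the
    train side with replacement each round.
    """
    if n_rounds < 1:
        raise ConfigurationError("n_rounds: must be >= 1")
    space = space or HyperSpace()
    space.validate()
    seeds = np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=n_rounds)

    rounds: list[ModelRound] = []
    groups = dataset.patient_ids if grouped else None
    for i in range(n_rounds):
        rng = np.random.default_rng(int(seeds[i]))
        split = make_split(dataset.target, ratio=ratio, rng=rng, groups=groups)
        if bootstrap:
            tr = split.train_indices
            split = SplitPlan(
                train_indices=tr[rng.integers(0, len(tr), size=len(tr))],
                test_indices=split.test_indices, ratio=ratio)
        hp = sample_hyperparams(rng, space)
        rounds.append(train_round(dataset, split, external, hp,
                                  seed=int(seeds[i]), round_id=i,
                                  n_estimators=n_estimators,
                                  use_early_stopping=use_early_stopping))

    result = MultiModelResult(all_rounds=rounds, auc_threshold=auc_threshold,
                              feature_names=list(dataset.feature_names),
                              master_seed=master_seed)
    logger.info("run_multimodel: %d/%d rounds retained (fraction %.3f, threshold %.2f)",
                len(result.retained), n_rounds, result.retention_fraction, auc_threshold)
    if result.status == "empty":
        logger.warning("run_multimodel: no rounds passed the AUROC filter")
    return result
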