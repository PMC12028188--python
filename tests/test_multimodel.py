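import numpy as np
import pytest

from conftest import FAST_ESTIMATORS, FAST_SPACE
from tyromark.exceptions import (
    ConfigurationError,
    DegenerateInputError,
    SchemaError,
    SplitError,
)
from tyromark.multimodel import (
    INTERNAL,
    HyperParams,
    HyperSpace,
    ModelRound,
    auroc,
    make_split,
    run_multimodel,
    sample_hyperparams,
    train_round,
)
from tyromark.preprocess import AnalysisDataset


def toy_dataset(n=60, n_features=4, seed=0, deterministic_feature=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    if deterministic_feature is None:
        y = rng.integers(0, 2, size=n)
    else:
        y = (X[:, deterministic_feature] > 0).astype(int)
    names = [f"f{i}" for i in range(n_features)]
    ids = np.array([f"P{i // 3}" for i in range(n)], dtype=object)
    return AnalysisDataset(X, names, y, np.array(["A"] * n, dtype=object),
                           ids, np.zeros(n, dtype=bool))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_reversed(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_all_ties(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 8, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            total = wins = 0.0
            for i in np.where(labels == 1)[0]:
                for j in np.where(labels == 0)[0]:
                    total += 1
                    if scores[i] > scores[j]:
                        wins += 1
                    elif scores[i] == scores[j]:
                        wins += 0.5
            assert auroc(scores, labels) == pytest.approx(wins / total, abs=1e-10)

    def test_complement_identity(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=20)  # tie-free
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        assert auroc(scores, labels) + auroc(scores, 1 - labels) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[:2] = [0, 1]
        base = auroc(scores, labels)
        assert auroc(np.exp(scores), labels) == base
        assert auroc(3 * scores + 7, labels) == base

    def test_single_class_error(self):
        with pytest.raises(DegenerateInputError):
            auroc([0.1, 0.2], [1, 1])


class TestMakeSplit:
    def test_sizes_and_disjoint(self):
        y = np.array([0, 1] * 5)
        plan = make_split(y, ratio=0.7, rng=np.random.default_rng(0))
        assert len(plan.train_indices) == 7
        assert len(plan.test_indices) == 3
        assert set(plan.train_indices).isdisjoint(plan.test_indices)
        assert set(plan.train_indices) | set(plan.test_indices) == set(range(10))

    def test_both_classes_each_side(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        for seed in range(20):
            plan = make_split(y, rng=np.random.default_rng(seed))
            assert len(np.unique(y[plan.train_indices])) == 2
            assert len(np.unique(y[plan.test_indices])) == 2

    def test_fresh_partitions_differ(self):
        y = np.array([0, 1] * 20)
        rng = np.random.default_rng(0)
        a = make_split(y, rng=rng)
        b = make_split(y, rng=rng)
        assert not np.array_equal(a.train_indices, b.train_indices)

    def test_grouped_mode_keeps_patients_together(self):
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        groups = np.array(["p1"] * 5 + ["p2"] * 5)
        plan = make_split(y, rng=np.random.default_rng(3), groups=groups)
        train_groups = set(groups[plan.train_indices])
        test_groups = set(groups[plan.test_indices])
        assert train_groups.isdisjoint(test_groups)

    def test_single_class_error(self):
        with pytest.raises(SplitError):
            make_split(np.ones(12, dtype=int), rng=np.random.default_rng(0))

    def test_too_small_error(self):
        with pytest.raises(SplitError):
            make_split(np.array([0, 1, 0, 1]), rng=np.random.default_rng(0))


class TestSampleHyperparams:
    def test_single_point_space(self):
        space = HyperSpace(tree_depth=(3, 3), learning_rate=(0.1, 0.1),
                           subsample_fraction=(0.8, 0.8), l2_penalty=(1e-3, 1e-3),
                           l1_penalty=(1e-4, 1e-4), positive_class_weight=(2.0, 2.0),
                           cv_folds=(5, 5))
        hp = sample_hyperparams(np.random.default_rng(0), space)
        assert hp == HyperParams(3, 0.1, 0.8, 1e-3, 1e-4, 2.0, 5)

    def test_integer_coverage(self):
        rng = np.random.default_rng(0)
        space = HyperSpace(tree_depth=(2, 6))
        seen = {sample_hyperparams(rng, space).tree_depth for _ in range(1000)}
        assert seen == {2, 3, 4, 5, 6}

    def test_ranges_respected(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            hp = sample_hyperparams(rng, HyperSpace())
            assert 0.01 <= hp.learning_rate <= 0.3
            assert 0.5 <= hp.subsample_fraction <= 1.0
            assert 2 <= hp.tree_depth <= 8
            assert 3 <= hp.cv_folds <= 10

    def test_inverted_range_rejected(self):
        with pytest.raises(ConfigurationError, match="tree_depth"):
            sample_hyperparams(np.random.default_rng(0),
                               HyperSpace(tree_depth=(5, 2)))


def _hp():
    return HyperParams(tree_depth=3, learning_rate=0.1, subsample_fraction=0.9,
                       l2_penalty=1e-6, l1_penalty=1e-6,
                       positive_class_weight=1.0, cv_folds=5)


class TestTrainRound:
    def test_separable_dataset(self):
        ds = toy_dataset(n=80, deterministic_feature=2, seed=3)
        plan = make_split(ds.target, rng=np.random.default_rng(0))
        mr = train_round(ds, plan, {}, _hp(), seed=0)
        assert mr.auroc_by_testset[INTERNAL] == 1.0
        assert int(np.argmax(mr.shap_by_testset[INTERNAL])) == 2

    def test_null_labels_auroc_near_half(self):
        hits = 0
        for seed in range(100):
            ds = toy_dataset(n=200, seed=seed)  # labels independent of X
            plan = make_split(ds.target, rng=np.random.default_rng(seed))
            mr = train_round(ds, plan, {}, _hp(), seed=seed, n_estimators=20)
            if 0.3 <= mr.auroc_by_testset[INTERNAL] <= 0.7:
                hits += 1
        assert hits >= 90

    def test_deterministic(self):
        ds = toy_dataset(n=60, deterministic_feature=0, seed=1)
        plan = make_split(ds.target, rng=np.random.default_rng(5))
        a = train_round(ds, plan, {}, _hp(), seed=9)
        b = train_round(ds, plan, {}, _hp(), seed=9)
        assert a.auroc_by_testset == b.auroc_by_testset
        for k in a.shap_by_testset:
            np.testing.assert_array_equal(a.shap_by_testset[k], b.shap_by_testset[k])

    def test_external_schema_mismatch(self):
        ds = toy_dataset(n=60, deterministic_feature=0)
        plan = make_split(ds.target, rng=np.random.default_rng(0))
        bad = toy_dataset(n=30, n_features=3, deterministic_feature=0)
        with pytest.raises(SchemaError, match="ext1"):
            train_round(ds, plan, {"ext1": bad}, _hp(), seed=0)

    def test_round_trip_json(self):
        ds = toy_dataset(n=60, deterministic_feature=0)
        plan = make_split(ds.target, rng=np.random.default_rng(0))
        mr = train_round(ds, plan, {}, _hp(), seed=0)
        back = ModelRound.from_json(mr.to_json())
        assert back.hyperparams == mr.hyperparams
        np.testing.assert_array_equal(back.shap_by_testset[INTERNAL],
                                      mr.shap_by_testset[INTERNAL])


class TestRunMultimodel:
    def test_single_round_separable(self):
        ds = toy_dataset(n=80, deterministic_feature=1, seed=2)
        res = run_multimodel(ds, {}, n_rounds=1, master_seed=0,
                             space=FAST_SPACE, n_estimators=FAST_ESTIMATORS)
        assert len(res.retained) == 1
        assert res.status == "ok"

    def test_unattainable_threshold_empty(self):
        ds = toy_dataset(n=80, deterministic_feature=1, seed=2)
        res = run_multimodel(ds, {}, n_rounds=3, auc_threshold=1.01,
                             master_seed=0, space=FAST_SPACE,
                             n_estimators=FAST_ESTIMATORS)
        assert res.retained == []
        assert res.status == "empty"

    def test_filter_correctness(self, mini_result):
        assert all(r.auroc_by_testset[INTERNAL] > 0.7
                   for r in mini_result.retained)

    def test_bit_reproducible(self):
        ds = toy_dataset(n=60, deterministic_feature=0, seed=4)
        a = run_multimodel(ds, {}, n_rounds=5, master_seed=42,
                           space=FAST_SPACE, n_estimators=FAST_ESTIMATORS)
        b = run_multimodel(ds, {}, n_rounds=5, master_seed=42,
                           space=FAST_SPACE, n_estimators=FAST_ESTIMATORS)
        assert [r.to_json() for r in a.all_rounds] == \
               [r.to_json() for r in b.all_rounds]

    def test_invalid_rounds(self):
        ds = toy_dataset(n=60, deterministic_feature=0)
        with pytest.raises(ConfigurationError):
            run_multimodel(ds, {}, n_rounds=0)
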