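import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from tyromark.consensus import (
    ImportanceTable,
    build_importance_table,
    compare_importance_distributions,
    consensus_cluster,
    corrected_importance,
    rank_variables,
)
from tyromark.exceptions import EmptyResultError, InsufficientDataError
from tyromark.multimodel import INTERNAL, HyperParams, ModelRound


def make_round(shap, auc, cohort=INTERNAL, round_id=0):
    hp = HyperParams(3, 0.1, 0.9, 1e-6, 1e-6, 1.0, 5)
    return ModelRound(round_id=round_id, hyperparams=hp,
                      auroc_by_testset={cohort: auc},
                      shap_by_testset={cohort: np.asarray(shap, dtype=float)},
                      seed=round_id)


FEATURES = ["a", "b"]


class TestCorrectedImportance:
    def test_single_product(self):
        rounds = [make_round([0.5, 0.1], 0.8)]
        ci = corrected_importance(rounds, INTERNAL, FEATURES)
        assert ci["a"] == pytest.approx(0.4)

    def test_mean_of_two(self):
        rounds = [make_round([0.5, 0.0], 0.8), make_round([0.25, 0.0], 0.8)]
        ci = corrected_importance(rounds, INTERNAL, FEATURES)
        assert ci["a"] == pytest.approx(0.3)

    def test_loop_accumulate_oracle(self):
        rng = np.random.default_rng(0)
        rounds = [make_round(rng.random(6), rng.uniform(0.5, 1.0), round_id=i)
                  for i in range(50)]
        names = list("abcdef")
        ci = corrected_importance(rounds, INTERNAL, names)
        for j, name in enumerate(names):
            acc = 0.0
            for r in rounds:
                acc += r.shap_by_testset[INTERNAL][j] * r.auroc_by_testset[INTERNAL]
            assert ci[name] == pytest.approx(acc / 50, abs=1e-12)

    def test_linear_in_shap(self):
        rng = np.random.default_rng(1)
        rounds = [make_round(rng.random(3), 0.9, round_id=i) for i in range(5)]
        doubled = [make_round(2 * r.shap_by_testset[INTERNAL], 0.9, round_id=i)
                   for i, r in enumerate(rounds)]
        a = corrected_importance(rounds, INTERNAL, list("xyz"))
        b = corrected_importance(doubled, INTERNAL, list("xyz"))
        pd.testing.assert_series_equal(2 * a, b, check_names=False)

    def test_replication_idempotent(self):
        rng = np.random.default_rng(2)
        rounds = [make_round(rng.random(3), rng.uniform(0.6, 1.0), round_id=i)
                  for i in range(7)]
        a = corrected_importance(rounds, INTERNAL, list("xyz"))
        b = corrected_importance(rounds * 3, INTERNAL, list("xyz"))
        pd.testing.assert_series_equal(a, b)

    def test_empty_refused(self):
        with pytest.raises(EmptyResultError):
            corrected_importance([], INTERNAL, FEATURES)

    def test_nan_auroc_rounds_skipped(self):
        rounds = [make_round([0.5, 0.5], float("nan")),
                  make_round([0.4, 0.2], 0.5, round_id=1)]
        ci = corrected_importance(rounds, INTERNAL, FEATURES)
        assert ci["a"] == pytest.approx(0.2)


def table_from(values, cohorts=("c1", "c2", "c3")):
    df = pd.DataFrame(values, columns=list(cohorts))
    return ImportanceTable(values=df, n_models={c: 10 for c in cohorts})


class TestRankVariables:
    def test_simple_order(self):
        t = table_from({"c1": [0.4, 0.1, 0.3]}, cohorts=("c1",))
        t.values.index = ["A", "B", "C"]
        rk = rank_variables(t, "c1")
        assert list(rk["variable"]) == ["A", "C", "B"]
        assert list(rk["rank"]) == [1, 2, 3]

    def test_ties_alphabetical_and_flagged(self):
        t = table_from({"c1": [0.2, 0.2, 0.2]}, cohorts=("c1",))
        t.values.index = ["zeta", "alpha", "mid"]
        rk = rank_variables(t, "c1")
        assert list(rk["variable"]) == ["alpha", "mid", "zeta"]
        assert rk["tied"].all()

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.random(8)
        t1 = table_from({"c1": vals}, cohorts=("c1",))
        t2 = table_from({"c1": vals * 17.0}, cohorts=("c1",))
        for t in (t1, t2):
            t.values.index = [f"v{i}" for i in range(8)]
        assert list(rank_variables(t1, "c1")["variable"]) == \
               list(rank_variables(t2, "c1")["variable"])

    def test_missing_cohort(self):
        t = table_from({"c1": [0.1, 0.2]}, cohorts=("c1",))
        with pytest.raises(KeyError):
            rank_variables(t, "nope")


class TestCompareImportanceDistributions:
    def test_identical_samples_p_one(self):
        rounds = [make_round([0.3, 0.3], 0.8, round_id=i) for i in range(10)]
        p = compare_importance_distributions(rounds, INTERNAL, FEATURES)
        assert p.loc["a", "b"] == 1.0

    def test_disjoint_support_significant(self):
        rng = np.random.default_rng(4)
        rounds = [make_round([1.0 + rng.random(), rng.random() * 0.1], 0.9,
                             round_id=i) for i in range(20)]
        p = compare_importance_distributions(rounds, INTERNAL, FEATURES)
        assert p.loc["a", "b"] < 0.01

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        rounds = [make_round(rng.random(4), rng.uniform(0.5, 1.0), round_id=i)
                  for i in range(15)]
        p = compare_importance_distributions(rounds, INTERNAL, list("wxyz"))
        pd.testing.assert_frame_equal(p, p.T)

    def test_single_round_refused(self):
        with pytest.raises(InsufficientDataError):
            compare_importance_distributions([make_round([0.1, 0.2], 0.9)],
                                             INTERNAL, FEATURES)


class TestConsensusCluster:
    def test_identical_profiles_merge_at_zero(self):
        t = table_from({"c1": [0.5, 0.5, 0.1], "c2": [0.4, 0.4, 0.0]},
                       cohorts=("c1", "c2"))
        t.values.index = ["x", "y", "z"]
        res = consensus_cluster(t)
        assert res.linkage[0, 2] == 0.0  # first merge height
        assert res.flat_labels["x"] == res.flat_labels["y"]

    def test_high_value_pair_is_top_cluster(self):
        t = table_from({"c1": [0.9, 0.1, 0.85, 0.05],
                        "c2": [0.8, 0.05, 0.8, 0.1],
                        "c3": [0.85, 0.1, 0.9, 0.05]})
        t.values.index = ["hi1", "lo1", "hi2", "lo2"]
        res = consensus_cluster(t)
        assert sorted(res.top_cluster) == ["hi1", "hi2"]

    def test_distance_matrix_matches_brute_force(self):
        rng = np.random.default_rng(6)
        mat = rng.random((7, 3))
        fast = squareform(pdist(mat))
        slow = np.zeros((7, 7))
        for i in range(7):
            for j in range(7):
                slow[i, j] = np.sqrt(((mat[i] - mat[j]) ** 2).sum())
        np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_all_zero_single_cluster(self, caplog):
        t = table_from({"c1": [0.0, 0.0], "c2": [0.0, 0.0]}, cohorts=("c1", "c2"))
        t.values.index = ["a", "b"]
        with caplog.at_level("WARNING"):
            res = consensus_cluster(t)
        assert len(set(res.flat_labels.values())) == 1
        assert "all-zero" in caplog.text

    def test_newick_wellformed(self):
        t = table_from({"c1": [0.9, 0.1, 0.5], "c2": [0.8, 0.2, 0.4]},
                       cohorts=("c1", "c2"))
        t.values.index = ["a", "b", "c"]
        res = consensus_cluster(t)
        assert res.newick.endswith(";")
        for name in ("a", "b", "c"):
            assert name in res.newick

    def test_degenerate_table_rejected(self):
        t = table_from({"c1": [0.1]}, cohorts=("c1",))
        t.values.index = ["only"]
        with pytest.raises(InsufficientDataError):
            consensus_cluster(t)


class TestEndToEnd:
    def test_table_from_mini_run(self, mini_result, split_datasets):
        train, external = split_datasets
        cohorts = [INTERNAL, "B", "C"]
        table = build_importance_table(mini_result.retained, cohorts,
                                       mini_result.feature_names)
        assert table.values.shape == (len(mini_result.feature_names), 3)
        assert (table.values.values >= 0).all()
        # entries bounded by the max SHAP over retained rounds (AUROC <= 1)
        for c in cohorts:
            max_shap = np.max([r.shap_by_testset[c]
                               for r in mini_result.retained], axis=0)
            assert (table.values[c].to_numpy() <= max_shap + 1e-12).all()
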