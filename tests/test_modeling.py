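"""Metrics, stratified folds, the nested-CV engine and learning curves."""

import numpy as np
import pytest

import nanotherm as nt
from nanotherm.exceptions import ContractError, SplitError
from nanotherm.features import EmbeddingMatrix
from nanotherm.modeling import (CVConfig, ModelSpec, compute_metrics,
                                learning_curve, run_nested_cv,
                                stratified_kfold)


class TestComputeMetrics:
    def test_identity_predictions(self):
        y = np.array([55.0, 60.0, 72.0, 81.0])
        m = compute_metrics(y, y)
        assert m.pearson_r == pytest.approx(1.0)
        assert m.spearman_rho == 1.0
        assert m.mae == 0.0
        assert m.sdr == pytest.approx(1.0)

    def test_constant_prediction_regresses_fully(self):
        y = np.array([55.0, 60.0, 72.0, 81.0])
        m = compute_metrics(y, np.full(4, y.mean()))
        assert m.sdr == 0.0
        assert m.mae == pytest.approx(np.mean(np.abs(y - y.mean())))

    def test_hand_formula_example(self):
        y = np.array([60.0, 70.0, 80.0])
        yhat = np.array([61.0, 69.0, 82.0])
        m = compute_metrics(y, yhat)
        # direct formula evaluation (independent arithmetic)
        dy, dh = y - y.mean(), yhat - yhat.mean()
        r = (dy @ dh) / np.sqrt((dy @ dy) * (dh @ dh))
        assert m.pearson_r == pytest.approx(r)
        assert m.spearman_rho == 1.0          # same ranking
        assert m.mae == pytest.approx(4 / 3)
        assert m.sdr == pytest.approx(np.std(yhat) / np.std(y))

    def test_zero_variance_flagged_not_crash(self):
        m = compute_metrics(np.full(5, 70.0), np.arange(5.0))
        assert m.degenerate and np.isnan(m.sdr)


class TestStratifiedKFold:
    def test_exact_balance_three_classes(self):
        labels = ["a", "b", "c"] * 3
        folds = stratified_kfold(labels, 3, seed=0)
        for _, te in folds:
            assert sorted(np.array(labels)[te]) == ["a", "b", "c"]

    def test_partition_law(self):
        labels = ["a"] * 30 + ["b"] * 21
        folds = stratified_kfold(labels, 3, seed=1)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test.tolist()) == list(range(51))
        for tr, te in folds:
            assert not set(tr) & set(te)

    def test_skewed_classes_within_one_of_proportionality(self):
        rng = np.random.default_rng(2)
        labels = rng.choice(["a", "b", "c"], size=100, p=[0.6, 0.3, 0.1])
        k = 4
        folds = stratified_kfold(labels, k, seed=2)
        for lab in "abc":
            total = int(np.sum(labels == lab))
            for _, te in folds:
                cnt = int(np.sum(labels[te] == lab))
                assert abs(cnt - total / k) <= 1

    def test_infeasible_class_named(self):
        with pytest.raises(SplitError, match="tiny"):
            stratified_kfold(["big"] * 10 + ["tiny"] * 2, 3)


def _linear_problem(n=150, d=20, noise=0.05, seed=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    beta = np.zeros(d)
    beta[:5] = [4, -3, 2, -1.5, 1]
    y = 70 + X @ beta + rng.normal(0, noise, n)
    mat = EmbeddingMatrix([f"s{i}" for i in range(n)], X, "external:sim")
    labels = np.array((["a", "b", "c"] * n)[:n])
    return mat, y, labels


class TestNestedCV:
    def test_planted_linear_signal_recovered_by_ridge(self):
        mat, y, labels = _linear_problem()
        res = run_nested_cv(mat, y, labels,
                            ModelSpec("ridge", "external:sim",
                                      grid={"alpha": [0.01, 0.1, 1.0]}),
                            CVConfig(seeds=(1,), inner_repeats=1))
        assert res.report.test_mean("spearman_rho") > 0.99

    def test_oof_bookkeeping_excludes_own_training_fold(self):
        mat, y, labels = _linear_problem(n=90)
        res = run_nested_cv(mat, y, labels,
                            ModelSpec("ridge", "external:sim",
                                      grid={"alpha": [1.0]}),
                            CVConfig(seeds=(1,), inner_repeats=1))
        tab = res.oof[1]
        assert np.all(np.isfinite(tab.matrix()))
        for i in range(len(tab.ids)):
            fold = tab.fold_of[i]
            tr, te = tab.folds[fold]
            assert i in te and i not in tr

    def test_poisoning_test_fold_labels_leaves_its_predictions_unchanged(self):
        mat, y, labels = _linear_problem(n=90)
        spec = ModelSpec("ridge", "external:sim", grid={"alpha": [1.0]})
        cfg = CVConfig(seeds=(1,), inner_repeats=1)
        res = run_nested_cv(mat, y, labels, spec, cfg)
        tab = res.oof[1]
        # the model predicting fold 0 never sees fold 0's labels: poisoning
        # them must not move fold 0's out-of-fold predictions
        _, te0 = tab.folds[0]
        y2 = y.copy()
        y2[te0] += 1000.0
        res2 = run_nested_cv(mat, y2, labels, spec, cfg)
        assert np.allclose(res2.oof[1].matrix()[te0],
                           tab.matrix()[te0], atol=1e-8)

    def test_reproducible_oof_for_deterministic_regressor(self):
        mat, y, labels = _linear_problem(n=90)
        spec = ModelSpec("ridge", "external:sim", grid={"alpha": [1.0, 10.0]})
        cfg = CVConfig(seeds=(3, 4), inner_repeats=1)
        a = run_nested_cv(mat, y, labels, spec, cfg)
        b = run_nested_cv(mat, y, labels, spec, cfg)
        for seed in (3, 4):
            assert np.array_equal(a.oof[seed].matrix(), b.oof[seed].matrix())

    def test_permutation_null_for_kernel_regressor(self, syn_small,
                                                   syn_small_onehot,
                                                   syn_small_strata):
        y = np.random.default_rng(8).permutation(syn_small.dataset.tms)
        res = run_nested_cv(syn_small_onehot, y, syn_small_strata.labels,
                            ModelSpec("support_vector", "onehot",
                                      grid={"C": [10.0], "epsilon": [0.5]},
                                      feature_k=(256,)),
                            CVConfig(seeds=(1, 2), inner_repeats=1))
        assert abs(res.report.test_mean("spearman_rho")) < 0.15


class TestLearningCurve:
    def test_train_rho_dominates_test_rho(self, syn_small, syn_small_onehot):
        lc = learning_curve(syn_small_onehot, syn_small.dataset.tms,
                            sizes=[20, 60], holdout=40, n_seeds=2)
        assert np.all(lc["train_rho_mean"] >= lc["test_rho_mean"])

    def test_size_budget_enforced(self, syn_small, syn_small_onehot):
        with pytest.raises(ContractError):
            learning_curve(syn_small_onehot, syn_small.dataset.tms,
                           sizes=[200], holdout=40)
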