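"""PCA descriptor filtering, GA-SVM subset search, and a-priori evaluation."""

import itertools

import numpy as np
import pytest

import sigscreen as sg
from sigscreen import AtomicSignature, GaConfig
from sigscreen.signature import DescriptorMatrix
from sigscreen.train import (
    SvmSpec,
    TrainedModel,
    _evaluate_subset,
    evaluate,
    ga_svm_search,
    pca_filter,
)

from conftest import FAST_GA, FAST_GRID


def fake_matrix(X, ids=None):
    """DescriptorMatrix over synthetic counts with placeholder signatures."""
    X = np.asarray(X)
    sigs = [AtomicSignature(0, f"[X{j}]") for j in range(X.shape[1])]
    return DescriptorMatrix(
        ids=ids or [f"c{i}" for i in range(X.shape[0])],
        signatures=sigs,
        X=X,
        heights=(0,),
    )


def fake_pca(matrix):
    n = len(matrix.signatures)
    return sg.PcaSelection(list(range(n)), np.ones(n), 1.0, "nonzero")


# --------------------------------------------------------------------------
# PCA filter


class TestPcaFilter:
    def test_constant_column_never_selected(self):
        rng = np.random.default_rng(0)
        X = rng.integers(1, 6, size=(20, 4))
        X[:, 2] = 3  # constant -> zero variance -> zero importance
        m = fake_matrix(X)
        sel = pca_filter(m, variance_cutoff=1.0, importance_rule="mean")
        assert 2 not in sel.selected
        assert sel.importance[2] == pytest.approx(0.0, abs=1e-10)

    def test_correlated_informative_columns_selected(self):
        # two perfectly correlated high-variance columns among weak noise
        rng = np.random.default_rng(3)
        signal = rng.integers(0, 10, size=30)
        X = np.column_stack([signal, signal, rng.integers(0, 2, size=(30, 4)) + 1])
        sel = pca_filter(fake_matrix(X), variance_cutoff=0.95, importance_rule="mean")
        assert {0, 1} <= set(sel.selected)

    def test_importance_matches_full_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 7, size=(25, 6)).astype(float)
        sel = pca_filter(fake_matrix(X), variance_cutoff=1.0, importance_rule="nonzero")
        # oracle: eigendecomposition of the covariance matrix
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        frac = evals / evals.sum()
        importance = (np.abs(evecs) * frac[None, :]).sum(axis=1)
        assert sel.importance == pytest.approx(importance, abs=1e-8)

    def test_cutoff_one_nonzero_rule_keeps_all_nonconstant(self):
        rng = np.random.default_rng(1)
        X = rng.integers(1, 5, size=(15, 5))
        X[:, 4] = 2
        sel = pca_filter(fake_matrix(X), variance_cutoff=1.0, importance_rule="nonzero")
        assert sel.selected == [0, 1, 2, 3]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pca_filter(fake_matrix(np.ones((1, 3))), 0.95)
        with pytest.raises(ValueError):
            pca_filter(fake_matrix(np.ones((4, 3))), 0.95)  # zero total variance


# --------------------------------------------------------------------------
# GA-SVM search


def toy_problem(seed):
    """6-column toy: class determined by column 0, others noise."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(40, 6))
    y = np.where(X[:, 0] > 0, 1.0, -1.0)
    if len(np.unique(y)) < 2:  # pragma: no cover
        y[0] = -y[0]
    return fake_matrix(X), y


class TestGaSvmSearch:
    @pytest.mark.parametrize("seed", range(1, 11))
    def test_ga_matches_exhaustive_search(self, seed):
        matrix, y = toy_problem(seed)
        folds, grid = 5, FAST_GRID
        # brute-force oracle over all 63 nonempty subsets
        best = min(
            _evaluate_subset(
                matrix.X.astype(float), y, np.array(cols), "classification",
                grid, 0.2, folds, seed,
            )[:2]
            for r in range(1, 7)
            for cols in itertools.combinations(range(6), r)
        )
        models = ga_svm_search(
            matrix, y, fake_pca(matrix), cost_grid=grid, folds=folds,
            ga=GaConfig(population=20, max_iter=15, stall_stop=5, seed=seed),
        )
        assert (models[0].cv_error, models[0].training_error) == pytest.approx(best)

    def test_elitism_best_fitness_never_degrades(self):
        matrix, y = toy_problem(0)
        history = []
        ga_svm_search(
            matrix, y, fake_pca(matrix), cost_grid=FAST_GRID, folds=5,
            ga=GaConfig(population=16, max_iter=12, stall_stop=12, seed=0),
            history=history,
        )
        assert len(history) >= 2
        assert all(b <= a for a, b in zip(history, history[1:]))

    def test_seeded_determinism(self):
        matrix, y = toy_problem(2)
        kwargs = dict(cost_grid=FAST_GRID, folds=5,
                      ga=GaConfig(population=16, max_iter=10, stall_stop=4, seed=9))
        run1 = ga_svm_search(matrix, y, fake_pca(matrix), **kwargs)
        run2 = ga_svm_search(matrix, y, fake_pca(matrix), **kwargs)
        assert [m.feature_subset for m in run1] == [m.feature_subset for m in run2]
        assert [m.weights for m in run1] == [m.weights for m in run2]

    def test_tied_models_share_selection_metrics_and_unique_subsets(self, trained_ensemble):
        ms = trained_ensemble.classifiers
        key = (ms[0].cv_error, ms[0].training_error)
        assert all((m.cv_error, m.training_error) == key for m in ms)
        subsets = [m.feature_subset for m in ms]
        assert len(subsets) == len(set(subsets))

    def test_single_class_labels_rejected(self):
        matrix, _ = toy_problem(1)
        with pytest.raises(ValueError):
            ga_svm_search(matrix, np.ones(40), fake_pca(matrix))

    def test_planted_rule_recovery_across_seeds(self, recovery_runs):
        """Retraining on fresh planted libraries recovers the planted signature."""
        recovered = sum(r["marker_recovered"] for r in recovery_runs)
        assert recovered >= 0.95 * len(recovery_runs)

    def test_regression_recovers_noiseless_linear_response(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 5, size=(30, 3)).astype(float)
        y = 0.5 * X[:, 0] - 0.2 * X[:, 1] + 1.0
        matrix = fake_matrix(X)
        errs = {}
        for cost in (0.01, 1.0):
            models = ga_svm_search(
                matrix, y, fake_pca(matrix), task="regression",
                cost_grid=[cost], folds=5, target_transform="linear",
                ga=GaConfig(population=12, max_iter=8, stall_stop=3, seed=0),
            )
            errs[cost] = models[0].training_error
        assert errs[1.0] < errs[0.01]
        assert errs[1.0] < 1e-2


# --------------------------------------------------------------------------
# a-priori evaluation


def score_model(scores, intercept=0.0):
    """Model + matrix pair whose decision values equal `scores + intercept`."""
    sig = AtomicSignature(0, "[X0]")
    matrix = fake_matrix(np.asarray(scores, dtype=int).reshape(-1, 1))
    model = TrainedModel(
        spec=SvmSpec(task="classification", cost=1.0),
        feature_subset=(sig,),
        weights={sig: 1.0},
        intercept=intercept,
        training_error=0.0,
        cv_error=0.0,
    )
    return model, matrix


def rank_auc(scores, truth):
    """Independent AUC oracle: normalized Mann-Whitney U statistic."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == -1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluate:
    def test_perfect_separation_gives_auc_one(self):
        model, matrix = score_model([5, 4, 3, 1, 0, 0], intercept=-2.0)
        truth = np.array([1, 1, 1, -1, -1, -1])
        out = evaluate(model, matrix, truth)
        assert out["auc"] == pytest.approx(1.0)
        assert out["accuracy"] == pytest.approx(1.0)

    def test_hit_rate_style_accuracy_four_of_seven(self):
        # 4 true positives, 3 false positives, nothing negative-predicted
        model, matrix = score_model([3, 3, 3, 3, 2, 2, 2])
        truth = np.array([1, 1, 1, 1, -1, -1, -1])
        out = evaluate(model, matrix, truth)
        assert out["accuracy"] == pytest.approx(4 / 7)

    def test_auc_agrees_with_rank_statistic_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            scores = rng.integers(0, 50, size=16)
            truth = np.array([1] * 8 + [-1] * 8)
            model, matrix = score_model(scores)
            out = evaluate(model, matrix, truth)
            assert out["auc"] == pytest.approx(rank_auc(scores, truth))

    def test_random_scores_average_auc_one_half(self):
        # Monte-Carlo oracle: 10,000 random score vectors on balanced labels
        rng = np.random.default_rng(4)
        truth = np.array([1] * 10 + [-1] * 10)
        aucs = []
        for _ in range(10_000):
            scores = rng.normal(size=20)
            aucs.append(rank_auc(scores, truth))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.01)

    def test_single_class_truth_rejected(self):
        model, matrix = score_model([1, 2, 3])
        with pytest.raises(ValueError):
            evaluate(model, matrix, np.array([1, 1, 1]))

    def test_cv_fold_assignment_depends_only_on_seed(self):
        from sigscreen.train import _class_cv_error

        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        y = np.array([1.0, -1.0] * 15)
        a = _class_cv_error(X, y, 0.5, 5, seed=3)
        b = _class_cv_error(X, y, 0.5, 5, seed=3)
        assert a == b


def test_ensemble_json_round_trip(tmp_path, trained_ensemble):
    path = tmp_path / "ensemble.json"
    sg.ensemble_to_json(trained_ensemble, path)
    back = sg.ensemble_from_json(path)
    assert len(back.classifiers) == len(trained_ensemble.classifiers)
    assert back.heights == trained_ensemble.heights
    assert back.train_stats == trained_ensemble.train_stats
    m0, m1 = trained_ensemble.classifiers[0], back.classifiers[0]
    assert m0.feature_subset == m1.feature_subset
    assert m0.weights == pytest.approx(m1.weights)
    if trained_ensemble.regressor is not None:
        assert back.regressor.target_transform == trained_ensemble.regressor.target_transform
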