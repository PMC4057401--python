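"""SVM training/prediction, CV, and the GA hyperparameter search."""

import numpy as np
import pytest

import _oracles
from aptaclass import classifier
from aptaclass.classifier import GAConfig, cross_validate, ga_optimize, predict, train_svm


def two_clouds(n_per=20, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 1, (n_per, 2)), rng.normal(sep, 1, (n_per, 2))]
    )
    y = np.array([1] * n_per + [2] * n_per)
    return X, y


def sklearn_dual_objective(model, X):
    """Dual objective of a trained model, from its stored coefficients."""
    sv, d = model.support_vectors, model.dual_coef
    d2 = ((sv[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-model.gamma * d2)
    return np.abs(d).sum() - 0.5 * d @ K @ d


class TestTrainPredict:
    def test_separable_clouds_perfect_training(self):
        X, y = two_clouds()
        model = train_svm(X, y, C=10, gamma=1)
        assert model.training_accuracy == 1.0
        assert np.array_equal(predict(model, X), y)

    def test_xor_separated_by_rbf(self):
        X = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        y = np.array([1, 1, 2, 2])
        model = train_svm(X, y, C=1000, gamma=1)
        assert np.array_equal(predict(model, X), y)

    def test_kkt_invariants(self):
        for seed in range(3):
            X, y = two_clouds(sep=2.0, seed=seed)
            C = 5.0
            model = train_svm(X, y, C=C, gamma=2.0)
            alpha = np.abs(model.dual_coef)
            assert np.all(alpha > 0) and np.all(alpha <= C + 1e-8)
            assert model.dual_coef.sum() == pytest.approx(0.0, abs=1e-6)
            f = model.decision_function(
                model.support_vectors * np.where(model.scale_range > 0, model.scale_range, 1)
                + model.scale_min
            )
            ypm = np.sign(model.dual_coef)
            unbounded = alpha < C - 1e-6
            assert np.all(np.abs((ypm * f)[unbounded] - 1.0) < 1e-3)

    def test_dual_objective_matches_qp_oracle(self):
        for seed in range(3):
            X, y = two_clouds(n_per=10, sep=1.5, seed=seed)
            model = train_svm(X, y, C=10.0, gamma=0.5)
            Xs = model.transform(X)
            ypm = np.where(y == 2, 1.0, -1.0)
            oracle = _oracles.svm_dual_optimum(Xs, ypm, C=10.0, gamma=0.5)
            assert sklearn_dual_objective(model, X) == pytest.approx(oracle, abs=1e-4)

    def test_far_point_gets_bias_label(self):
        X, y = two_clouds()
        model = train_svm(X, y, C=10, gamma=5)
        far = np.array([[1e4, -1e4]])
        assert predict(model, far)[0] == (2 if model.bias > 0 else 1)

    def test_training_accuracy_nondecreasing_in_C(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (40, 2))
        y = np.where(X[:, 0] + 0.5 * rng.normal(size=40) > 0, 2, 1)
        if len(set(y)) < 2:  # pragma: no cover
            pytest.skip("degenerate draw")
        accs = [train_svm(X, y, C, 1.0).training_accuracy for C in (0.1, 10, 1000)]
        assert accs == sorted(accs)

    def test_errors(self):
        X, y = two_clouds()
        with pytest.raises(classifier.ClassifierError):
            train_svm(X, np.ones(len(X), dtype=int), 1, 1)
        with pytest.raises(classifier.ClassifierError):
            train_svm(X * np.nan, y, 1, 1)
        with pytest.raises(classifier.ClassifierError):
            train_svm(X, y, -1, 1)
        model = train_svm(X, y, 1, 1)
        with pytest.raises(classifier.ClassifierError):
            predict(model, np.zeros((3, 5)))

    def test_serialization_roundtrip(self, tmp_path):
        X, y = two_clouds()
        model = train_svm(X, y, C=7, gamma=3)
        path = tmp_path / "model.json"
        model.save(path)
        again = classifier.SVMModel.load(path)
        assert np.array_equal(predict(again, X), predict(model, X))
        assert again.C == model.C and again.gamma == model.gamma


class TestCrossValidate:
    def test_separable_is_perfect(self):
        X, y = two_clouds()
        assert cross_validate(X, y, C=10, gamma=1, seed=1) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        y = np.array([1, 2] * 30)
        a = cross_validate(X, y, 5, 0.5, seed=11)
        b = cross_validate(X, y, 5, 0.5, seed=11)
        assert a == b

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 4))
        hits = 0
        for seed in range(10):
            y = rng.permutation([1, 2] * 100)
            acc = cross_validate(X, y, C=10, gamma=1, seed=seed)
            hits += 0.4 <= acc <= 0.6
        assert hits >= 8


class TestGA:
    def test_history_nondecreasing_and_bounds(self):
        X, y = two_clouds(n_per=12, sep=2.0, seed=1)
        config = GAConfig(population_size=8, generations=10, seed=4)
        res = ga_optimize(X, y, config)
        assert all(b >= a for a, b in zip(res.history, res.history[1:]))
        assert 1 <= res.C <= 1000 and 1 <= res.gamma <= 1000
        assert len(res.history) == config.generations + 1

    def test_beats_or_ties_grid_search(self):
        for seed in (0, 1, 2):
            X, y = two_clouds(n_per=15, sep=3.0, seed=seed)
            grid_best = max(
                cross_validate(X, y, C, g, seed=seed)
                for C in np.logspace(0, 3, 10)
                for g in np.logspace(0, 3, 10)
            )
            res = ga_optimize(X, y, GAConfig(population_size=20, generations=25, seed=seed))
            assert res.cv_accuracy >= grid_best - 1e-12
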