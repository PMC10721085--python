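"""Readout training and classification: standardization, ridge, logistic."""

import warnings

import numpy as np
import pytest

from swayrc import (LabelSeries, ReadoutModel, accuracy, classify,
                    cross_entropy, evaluate_readout, fit_multinomial_logistic,
                    fit_readout, fit_ridge, moving_average, predict_scores,
                    standardize_fit, standardize_fit_apply)


def ridge_oracle(X, Y, alpha):
    """Direct evaluation of the closed form with an explicit inverse."""
    return Y.T @ X @ np.linalg.inv(X.T @ X + alpha * np.eye(X.shape[1]))


def ridge_augmented_oracle(X, Y, alpha):
    """Least squares on the alpha-augmented system."""
    m = X.shape[1]
    Xa = np.vstack([X, np.sqrt(alpha) * np.eye(m)])
    Ya = np.vstack([Y, np.zeros((m, Y.shape[1]))])
    W, *_ = np.linalg.lstsq(Xa, Ya, rcond=None)
    return W.T


class TestStandardize:
    def test_hand_example_population_variance(self):
        col = np.array([[1.0], [2.0], [3.0]])
        std, _, stats = standardize_fit_apply(col)
        assert np.allclose(std.ravel(), [-1.22474487, 0.0, 1.22474487])
        assert stats.variance[0] == pytest.approx(2.0 / 3.0)

    def test_idempotent(self, rng):
        X = rng.standard_normal((50, 3))
        X = (X - X.mean(0)) / X.std(0)
        again, _, _ = standardize_fit_apply(X)
        assert np.allclose(again, X, atol=1e-12)

    def test_constant_column_floored_with_warning(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(RuntimeWarning):
            std, _, _ = standardize_fit_apply(X)
        assert np.allclose(std[:, 0], 0.0)

    def test_stats_from_train_only(self, rng):
        X_train = rng.standard_normal((30, 2)) + 5.0
        X_other = rng.standard_normal((10, 2))
        _, other, stats = standardize_fit_apply(X_train, X_other)
        assert np.allclose(other, (X_other - stats.mean)
                           / np.sqrt(stats.variance))


class TestRidge:
    def test_self_regression_limit(self, rng):
        X = rng.standard_normal((40, 4))
        W = fit_ridge(X, X, alpha=1e-10)
        assert np.allclose(W, np.eye(4), atol=1e-5)

    def test_explicit_inverse_oracle(self, rng):
        X = rng.standard_normal((6, 3)) * 10
        Y = rng.standard_normal((6, 2))
        W = fit_ridge(X, Y, alpha=1e6)
        assert np.allclose(W, ridge_oracle(X, Y, 1e6), atol=1e-12)

    def test_large_alpha_shrinks_to_zero(self, rng):
        X = rng.standard_normal((20, 5))
        Y = rng.standard_normal((20, 2))
        assert np.abs(fit_ridge(X, Y, alpha=1e14)).max() < 1e-9

    def test_augmented_system_oracle_random_instances(self, rng):
        for _ in range(10):
            n, m, c = rng.integers(5, 51), rng.integers(2, 21), 3
            X = rng.standard_normal((n, m)) * rng.uniform(0.1, 20)
            Y = rng.standard_normal((n, c))
            alpha = float(rng.uniform(1e-2, 1e6))
            W = fit_ridge(X, Y, alpha)
            ref = ridge_augmented_oracle(X, Y, alpha)
            assert np.allclose(W, ref, rtol=1e-8, atol=1e-10)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.linear_model import Ridge
        X = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 4))
        W = fit_ridge(X, Y, alpha=12.5)
        sk = Ridge(alpha=12.5, fit_intercept=False).fit(X, Y)
        assert np.allclose(W, sk.coef_, atol=1e-8)

    def test_rejects_bad_input(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            fit_ridge(X, np.zeros((10, 2)), alpha=0.0)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_ridge(X, np.zeros((10, 2)), alpha=1.0)


class TestScoresAndClassification:
    def test_zero_weights_zero_scores(self, rng):
        model = ReadoutModel("ridge", 3, W_out=np.zeros((3, 4)))
        assert np.all(predict_scores(model, rng.standard_normal((5, 4))) == 0)

    def test_one_hot_weights_pick_column(self, rng):
        W = np.zeros((2, 3))
        W[0, 1] = 1.0
        X = rng.standard_normal((6, 3))
        scores = predict_scores(ReadoutModel("ridge", 2, W_out=W), X)
        assert np.allclose(scores[:, 0], X[:, 1])

    def test_column_mismatch(self, rng):
        model = ReadoutModel("ridge", 2, W_out=np.zeros((2, 3)))
        with pytest.raises(ValueError):
            predict_scores(model, rng.standard_normal((4, 5)))

    def test_tau_one_identity(self, rng):
        scores = rng.standard_normal((20, 4))
        smoothed, pred = classify(scores, 1)
        assert np.array_equal(smoothed, scores)
        assert np.array_equal(pred, scores.argmax(axis=1))

    def test_constant_scores_constant_class(self):
        scores = np.tile([0.1, 0.2, 0.7], (15, 1))
        _, pred = classify(scores, 5)
        assert np.all(pred == 2)

    def test_alternating_rows_pairwise_means(self):
        scores = np.array([[1.0, 0.0], [0.0, 1.0]] * 3)
        smoothed, _ = classify(scores, 2)
        # hand computation: first row truncated, then pairwise means
        assert np.allclose(smoothed[0], [1.0, 0.0])
        assert np.allclose(smoothed[1:], 0.5)

    def test_segment_reset(self):
        scores = np.vstack([np.tile([1.0, 0.0], (5, 1)),
                            np.tile([0.0, 1.0], (5, 1))])
        _, pred_plain = classify(scores, 4)
        _, pred_reset = classify(scores, 4, segment_starts=np.array([5]))
        assert np.array_equal(pred_reset, [0] * 5 + [1] * 5)
        assert not np.array_equal(pred_plain, pred_reset)  # smearing

    def test_ties_break_to_smallest_class(self):
        _, pred = classify(np.zeros((3, 4)), 1)
        assert np.all(pred == 0)

    def test_moving_average_requires_positive_tau(self):
        with pytest.raises(ValueError):
            moving_average(np.zeros((4, 2)), 0)


class TestAccuracyAndCrossEntropy:
    def test_accuracy_cases(self):
        assert accuracy(np.array([1, 2, 3]), np.array([1, 2, 3])) == 1.0
        assert accuracy(np.array([1, 1, 1, 0]),
                        np.array([1, 1, 1, 1])) == 0.75

    def test_chance_level_constant_prediction(self):
        labels = np.repeat(np.arange(6), 100)
        assert accuracy(np.zeros(600, int), labels) == pytest.approx(1 / 6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            accuracy(np.zeros(3), np.zeros(4))

    def test_perfect_probabilities_zero_loss(self):
        Y = np.eye(4)
        assert cross_entropy(Y, Y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_probabilities_log_c(self):
        scores = np.full((10, 6), 1 / 6)
        Y = np.zeros((10, 6))
        Y[:, 0] = 1
        assert cross_entropy(scores, Y) == pytest.approx(np.log(6))

    def test_two_step_hand_value(self):
        scores = np.array([[0.8, 0.2], [0.4, 0.6]])
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        expected = -(np.log(0.8) + np.log(0.6)) / 2
        assert cross_entropy(scores, Y) == pytest.approx(expected)

    def test_clipping_handles_zero_scores(self):
        scores = np.array([[0.0, 1.0]])
        Y = np.array([[1.0, 0.0]])
        assert np.isfinite(cross_entropy(scores, Y))


class TestMultinomialLogistic:
    def test_zero_features_balanced_uniform(self):
        X = np.zeros((60, 3))
        labels = np.repeat(np.arange(3), 20)
        beta, _ = fit_multinomial_logistic(X, labels)
        assert np.allclose(beta, 0.0, atol=1e-6)
        model = ReadoutModel("logistic", 3, beta=beta)
        probs = predict_scores(model, np.zeros((4, 3)))
        assert np.allclose(probs, 1 / 3)

    def test_binary_reduces_to_sigmoid(self, rng):
        X = rng.standard_normal((80, 2))
        labels = (X[:, 0] + 0.3 * rng.standard_normal(80) > 0).astype(int)
        beta, _ = fit_multinomial_logistic(X, labels, max_iter=500)
        assert beta.shape == (1, 3)
        logits = beta[0, 0] + X @ beta[0, 1:]
        p0 = 1.0 / (1.0 + np.exp(-logits))  # sigmoid for class 0
        model = ReadoutModel("logistic", 2, beta=beta)
        probs = predict_scores(model, X)
        assert np.allclose(probs[:, 0], p0, atol=1e-9)

    def test_probability_rows_sum_to_one(self, rng):
        X = rng.standard_normal((50, 4))
        labels = rng.integers(0, 3, 50)
        beta, _ = fit_multinomial_logistic(X, labels, max_iter=200)
        probs = predict_scores(ReadoutModel("logistic", 3, beta=beta), X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_separable_data_perfect_training_accuracy(self):
        X = np.vstack([np.full((20, 2), -2.0), np.full((20, 2), 2.0)])
        labels = np.repeat([0, 1], 20)
        beta, converged = fit_multinomial_logistic(X, labels, max_iter=1500)
        probs = predict_scores(ReadoutModel("logistic", 2, beta=beta), X)
        assert accuracy(probs.argmax(1), labels) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_multinomial_logistic(np.zeros((5, 2)), np.zeros(5, int))


class TestFitEvaluatePipeline:
    def test_noise_free_separable_reaches_one(self, rng):
        centers = rng.standard_normal((4, 6)) * 10
        labels = np.repeat(np.arange(4), 50)
        X = centers[labels] + 0.01 * rng.standard_normal((200, 6))
        model = fit_readout(X, labels, alpha=1e-3)
        out = evaluate_readout(model, X, labels, tau_ma=1)
        assert out.accuracy == 1.0

    def test_model_json_round_trip(self, tmp_path, rng):
        X = rng.standard_normal((30, 4))
        labels = rng.integers(0, 3, 30)
        model = fit_readout(X, labels, alpha=10.0, standardize=True,
                            n_classes=3)
        path = model.to_json(tmp_path / "model.json")
        back = ReadoutModel.from_json(path)
        assert np.allclose(back.W_out, model.W_out)
        assert np.allclose(predict_scores(back, X), predict_scores(model, X))

    def test_label_series_one_hot(self):
        ls = LabelSeries(np.array([0, 2, 1]), 3)
        oh = ls.one_hot()
        assert np.array_equal(oh.sum(axis=1), [1, 1, 1])
        assert oh[1, 2] == 1.0

    def test_label_independent_predictor_converges_to_chance(self, rng):
        # Monte-Carlo: ridge on one noise unit stays at 1/C for balanced C
        labels = np.repeat(np.arange(4), 250)
        accs = []
        for _ in range(20):
            X = rng.standard_normal((1000, 1))
            model = fit_readout(X, labels, alpha=1e6, n_classes=4)
            accs.append(evaluate_readout(model, X, labels, tau_ma=1).accuracy)
        assert abs(np.mean(accs) - 0.25) < 0.03
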