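"""Shrunken-centroid classifier: fit, soft-threshold, predict, CV selection."""

import numpy as np
import pytest

from nof1seq.errors import TrainingError
from nof1seq.nsc import (
    CentroidModel,
    cross_validate,
    fit_centroids,
    predict,
    shrink,
    train,
)
from nof1seq.simulate import simulate_class_data


def gaussian_oracle_label(x, stats):
    """Diagonal-covariance Gaussian classifier with variances (s_j + s0)^2."""
    scale2 = (stats.pooled_sd + stats.s0) ** 2
    ok = scale2 > 0
    disc = [
        ((x[ok] - c[ok]) ** 2 / scale2[ok]).sum() - 2 * np.log(p)
        for c, p in zip(stats.class_centroids, stats.priors)
    ]
    return stats.classes[int(np.argmin(disc))]


class TestFitCentroids:
    def test_one_gene_toy(self):
        X = np.array([[1.0], [1.0], [3.0], [3.0]])
        y = ["A", "A", "B", "B"]
        stats = fit_centroids(X, y)
        assert stats.overall_centroid[0] == 2.0
        np.testing.assert_allclose(stats.class_centroids[:, 0], [1.0, 3.0])
        assert stats.pooled_sd[0] == 0.0
        np.testing.assert_allclose(stats.priors, [0.5, 0.5])
        np.testing.assert_allclose(stats.m_k, np.sqrt(1 / 2 + 1 / 4))

    def test_identical_class_data_gives_zero_d(self):
        X = np.vstack([np.full((3, 4), 1.0), np.full((3, 4), 1.0)])
        y = ["A"] * 3 + ["B"] * 3
        stats = fit_centroids(X, y)
        np.testing.assert_allclose(stats.d, 0.0)

    def test_small_class_rejected(self):
        with pytest.raises(TrainingError, match="fewer than 2"):
            fit_centroids(np.zeros((3, 2)), ["A", "A", "B"])


class TestShrink:
    @pytest.fixture()
    def rand_stats(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(30, 20))
        y = np.repeat(["A", "B", "C"], 10)
        X[:10, :5] += 1.5
        return fit_centroids(X, y)

    def test_delta_zero_is_identity(self, rand_stats):
        model = shrink(rand_stats, 0.0)
        np.testing.assert_allclose(model.shrunk_centroids, rand_stats.class_centroids,
                                   atol=1e-12)
        assert model.selected.all()

    def test_full_collapse(self, rand_stats):
        dmax = np.abs(rand_stats.d).max()
        model = shrink(rand_stats, dmax + 0.1)
        np.testing.assert_allclose(
            model.shrunk_centroids,
            np.tile(rand_stats.overall_centroid, (3, 1)),
            atol=1e-12,
        )
        assert not model.selected.any()

    def test_soft_threshold_arithmetic(self):
        # d = 2.5 shrunk by delta 1 leaves 1.5 on the standardized scale
        assert np.sign(2.5) * max(abs(2.5) - 1.0, 0) == 1.5
        X = np.array([[0.0], [0.2], [5.0], [4.8]])
        stats = fit_centroids(X, ["A", "A", "B", "B"])
        model = shrink(stats, 1.0)
        d = stats.d
        expected = stats.overall_centroid + stats.m_k * (
            stats.pooled_sd[0] + stats.s0
        ) * (np.sign(d[:, 0]) * np.maximum(np.abs(d[:, 0]) - 1.0, 0))
        np.testing.assert_allclose(model.shrunk_centroids[:, 0], expected)

    def test_selected_count_monotone_in_delta(self, rand_stats):
        dmax = np.abs(rand_stats.d).max()
        counts = [
            int(shrink(rand_stats, d).selected.sum())
            for d in np.linspace(0, dmax, 30)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPredict:
    def test_matches_gaussian_oracle_at_delta_zero(self):
        """At delta = 0 the classifier is a diagonal Gaussian with variances
        (s_j + s0)^2 and priors pi_k, checked on 100 random datasets."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_genes = int(rng.integers(3, 10))
            X = rng.normal(size=(24, n_genes))
            y = np.repeat(["A", "B", "C"], 8)
            X[:8] += rng.normal(0, 0.5, size=n_genes)
            stats = fit_centroids(X, y)
            model = shrink(stats, 0.0)
            x = rng.normal(size=n_genes)
            assert predict(model, x).label == gaussian_oracle_label(x, stats)

    def test_centroid_is_classified_to_its_class(self):
        X, y = simulate_class_data(n_classes=3, n_per_class=10, n_genes=50,
                                   n_shifted=9, shift=3.0, seed=1)
        model = shrink(fit_centroids(X, y), 0.0)
        for k, cls in enumerate(model.classes):
            assert predict(model, model.shrunk_centroids[k]).label == cls

    def test_collapsed_model_predicts_by_priors(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 5))
        y = ["A"] * 7 + ["B"] * 3
        stats = fit_centroids(X, y)
        model = shrink(stats, np.abs(stats.d).max() + 1)
        pred = predict(model, np.zeros(5))
        assert pred.uninformative
        assert pred.label == "A"
        np.testing.assert_allclose(
            [pred.probabilities["A"], pred.probabilities["B"]], [0.7, 0.3]
        )

    def test_one_gene_toy_prediction(self):
        X = np.array([[1.0], [1.0], [3.0], [3.0]])
        stats = fit_centroids(X, ["A", "A", "B", "B"])
        model = shrink(stats, 0.0)
        # s_j = 0 and s0 = median(s_j) = 0: no usable gene, priors are equal,
        # ties resolve to the first class
        pred = predict(model, np.array([1.0]))
        assert pred.label == "A"

    def test_probabilities_sum_to_one_and_label_attains_max(self):
        X, y = simulate_class_data(seed=5)
        model = shrink(fit_centroids(X, y), 0.5)
        rng = np.random.default_rng(8)
        for _ in range(20):
            pred = predict(model, rng.normal(size=X.shape[1]))
            assert sum(pred.probabilities.values()) == pytest.approx(1.0, abs=1e-9)
            assert pred.label == max(pred.probabilities, key=pred.probabilities.get)

    def test_probabilities_invariant_to_discriminant_shift(self):
        # doubling all priors' -2 ln pi by a constant leaves softmax unchanged:
        # verified via the uninformative path where disc = -2 ln pi + const
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 4))
        y = ["A"] * 6 + ["B"] * 6
        stats = fit_centroids(X, y)
        model = shrink(stats, 0.0)
        x = rng.normal(size=4)
        p1 = predict(model, x)
        disc = np.array([p1.discriminants[c] for c in model.classes])
        shifted = np.exp(-(disc + 17.0) / 2)
        np.testing.assert_allclose(
            shifted / shifted.sum(),
            [p1.probabilities[c] for c in model.classes],
            atol=1e-12,
        )

    def test_missing_genes_imputed_with_warning(self):
        X, y = simulate_class_data(n_classes=2, n_per_class=5, n_genes=10,
                                   n_shifted=4, shift=2.0, seed=2)
        model = shrink(fit_centroids(X, y), 0.0)
        x = model.shrunk_centroids[1].copy()
        x[3] = np.nan
        with pytest.warns(UserWarning, match="imputed 1 missing"):
            pred = predict(model, x)
        assert pred.label == model.classes[1]


class TestCrossValidateAndTrain:
    def test_perfect_separation_zero_error(self):
        X, y = simulate_class_data(n_classes=2, n_per_class=20, n_genes=40,
                                   n_shifted=10, shift=6.0, seed=4)
        err = cross_validate(X, y, [0.0, 0.5], k_folds=5, seed=0)
        assert err[0] == 0.0

    def test_permuted_labels_near_chance(self):
        X, y = simulate_class_data(n_classes=2, n_per_class=30, n_genes=50,
                                   n_shifted=10, shift=2.0, seed=10)
        rng = np.random.default_rng(11)
        y_perm = rng.permutation(y)
        err = cross_validate(X, y_perm, [0.0], k_folds=5, seed=0)
        assert 0.4 <= err[0] <= 0.6

    def test_single_delta_grid_selected(self):
        X, y = simulate_class_data(n_classes=2, n_per_class=10, n_genes=20,
                                   n_shifted=6, shift=2.0, seed=12)
        model = train(X, y, delta_grid=[0.7], k_folds=3, seed=0)
        assert model.delta == 0.7

    def test_tie_breaks_toward_largest_delta(self):
        X, y = simulate_class_data(n_classes=2, n_per_class=20, n_genes=40,
                                   n_shifted=10, shift=6.0, seed=13)
        model = train(X, y, delta_grid=[0.0, 0.1, 0.2], k_folds=5, seed=0)
        # perfectly separable: all three deltas give error 0, largest wins
        assert model.delta == 0.2

    def test_heldout_error_on_four_class_design(self):
        """Four classes, 2-pooled-SD shifts on 30 of 500 genes, 40/class:
        held-out error stays at or below 0.1."""
        X_train, y_train = simulate_class_data(seed=100)
        X_test, y_test = simulate_class_data(n_per_class=20, seed=101)
        model = train(X_train, y_train, seed=0)
        preds = [predict(model, x).label for x in X_test]
        error = np.mean([p != t for p, t in zip(preds, y_test)])
        assert error <= 0.1

    def test_serialization_round_trip(self):
        X, y = simulate_class_data(n_classes=2, n_per_class=10, n_genes=20,
                                   n_shifted=6, shift=2.0, seed=14)
        model = train(X, y, delta_grid=[0.3], k_folds=3, seed=0)
        clone = CentroidModel.from_dict(model.to_dict())
        x = np.linspace(-1, 1, 20)
        assert predict(clone, x).label == predict(model, x).label
        assert predict(clone, x).probabilities == predict(model, x).probabilities
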