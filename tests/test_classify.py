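"""Classification stage: PCA, Fisher LDA, ELM, neuron range, accuracy."""

import numpy as np
import pytest

import bloodspec as bs
from bloodspec.classify import _activation


class TestPCA:
    def test_rank_one_data_single_component(self):
        t = np.linspace(0, 1, 30)
        direction = np.random.default_rng(0).normal(size=10)
        X = np.outer(t, direction)
        model = bs.pca_fit(X, n_components=1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_training_mean_maps_to_origin(self):
        X = np.random.default_rng(1).normal(size=(25, 6))
        model = bs.pca_fit(X, n_components=3)
        np.testing.assert_allclose(
            bs.pca_transform(model, X.mean(axis=0)[None, :]), 0.0, atol=1e-10
        )

    def test_full_rank_reconstruction(self):
        X = np.random.default_rng(2).normal(size=(20, 5))
        model = bs.pca_fit(X, n_components=5)
        scores = bs.pca_transform(model, X)
        recon = scores @ model.loadings.T + model.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_loadings_orthonormal_ratios_sorted(self):
        X = np.random.default_rng(3).normal(size=(50, 8))
        model = bs.pca_fit(X, n_components=4)
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(4), atol=1e-10
        )
        r = model.explained_variance_ratio
        assert np.all(np.diff(r) <= 1e-12) and r.sum() <= 1 + 1e-12

    def test_low_variance_warning(self):
        X = np.random.default_rng(4).normal(size=(100, 20))  # isotropic
        with pytest.warns(UserWarning):
            bs.pca_fit(X, n_components=2)


class TestFisherLDA:
    def test_six_classes_in_three_dims_give_three_dfs(self):
        rng = np.random.default_rng(5)
        centers = rng.normal(scale=10, size=(6, 3))
        X = np.vstack([c + rng.normal(scale=0.2, size=(20, 3)) for c in centers])
        labels = np.repeat(np.arange(6), 20)
        model = bs.fisher_lda_fit(X, labels)
        assert model.coef.shape == (3, 3)
        assert model.centroids.shape == (6, 3)

    def test_separated_gaussians_perfectly_classified(self):
        rng = np.random.default_rng(6)
        X = np.vstack(
            [rng.normal(0, 0.3, size=(40, 4)), rng.normal(20, 0.3, size=(40, 4))]
        )
        labels = np.repeat(["a", "b"], 40)
        model = bs.fisher_lda_fit(X[::2], labels[::2])
        pred = bs.fisher_lda_predict(model, X[1::2])
        assert bs.accuracy(labels[1::2], pred).accuracy_pct == 100.0

    def test_centroids_are_fixed_points(self):
        rng = np.random.default_rng(7)
        centers = rng.normal(scale=8, size=(4, 3))
        X = np.vstack([c + rng.normal(scale=0.3, size=(15, 3)) for c in centers])
        labels = np.repeat(np.arange(4), 15)
        model = bs.fisher_lda_fit(X, labels)
        class_means = np.vstack([X[labels == c].mean(axis=0) for c in range(4)])
        pred = bs.fisher_lda_predict(model, class_means)
        np.testing.assert_array_equal(pred, np.arange(4))


class TestELM:
    def test_interpolation_regime(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        model = bs.elm_train(X, y, n_hidden=30, activation="sigmoid", seed=0)
        assert bs.rmse(y, bs.elm_predict(model, X)) < 1e-6

    def test_output_weights_match_least_squares_oracle(self):
        # independent SVD-based solver on the same hidden matrix
        rng = np.random.default_rng(9)
        for trial in range(100):
            n, d, h = rng.integers(10, 40), rng.integers(2, 6), rng.integers(2, 15)
            X = rng.normal(size=(n, d))
            y = rng.normal(size=n)
            model = bs.elm_train(X, y, n_hidden=int(h), activation="sigmoid", seed=trial)
            H = _activation("sigmoid")(X @ model.input_weights + model.biases)
            oracle = np.linalg.lstsq(H, y, rcond=None)[0]
            assert np.abs(model.output_weights.ravel() - oracle).max() < 1e-8

    def test_same_seed_same_predictions(self):
        X = np.random.default_rng(10).normal(size=(20, 4))
        y = np.arange(20.0)
        a = bs.elm_train(X, y, 7, seed=3)
        b = bs.elm_train(X, y, 7, seed=3)
        np.testing.assert_array_equal(bs.elm_predict(a, X), bs.elm_predict(b, X))

    def test_hardlim_is_step_function(self):
        f = _activation("hardlim")
        np.testing.assert_array_equal(f(np.array([-1.0, 0.0, 2.0])), [0.0, 0.0, 1.0])

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            bs.elm_train(np.array([[np.nan, 1.0]]), np.array([1.0]), 2)


class TestNeuronRange:
    def test_direct_evaluation(self):
        assert bs.hidden_neuron_range(100, 1, 1) == (5, 25)

    def test_degenerate_alpha_range(self):
        low, high = bs.hidden_neuron_range(360, 3, 1, alpha_range=(4, 4))
        assert low == high == round(360 / (4 * 4))

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            bs.hidden_neuron_range(0, 3, 1)


class TestAccuracy:
    def test_all_correct(self):
        rep = bs.accuracy(["a", "b"], ["a", "b"])
        assert rep.accuracy_pct == 100.0
        assert np.array_equal(rep.confusion, np.eye(2, dtype=int))

    def test_bounds_and_diagonal_iff_perfect(self):
        rep = bs.accuracy([1, 1, 2, 2], [1, 2, 2, 2])
        assert 0 <= rep.accuracy_pct <= 100
        off_diag = rep.confusion.sum() - np.trace(rep.confusion)
        assert (rep.accuracy_pct == 100) == (off_diag == 0)

    def test_confusion_identities(self):
        rep = bs.accuracy([0, 1, 2, 0], [0, 2, 2, 1])
        assert rep.n_correct == np.trace(rep.confusion)
        assert rep.n_total == rep.confusion.sum()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bs.accuracy([1, 2], [1])


class TestSweep:
    def test_grid_size_and_self_consistency(self):
        rng = np.random.default_rng(11)
        centers = rng.normal(scale=10, size=(3, 2))
        X = np.vstack([c + rng.normal(scale=0.3, size=(30, 2)) for c in centers])
        labels = np.repeat(["x", "y", "z"], 30)
        curve, best, model = bs.sweep_elm(
            X[::2], labels[::2], X[1::2], labels[1::2],
            classes=np.array(["x", "y", "z"]),
            neuron_range=(1, 10), seed=1,
        )
        assert len(curve) == 3 * 10
        assert any(
            e.activation == best.activation
            and e.n_hidden == best.n_hidden
            and e.test_accuracy == best.test_accuracy
            for e in curve
        )
        assert best.test_accuracy == max(e.test_accuracy for e in curve)
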