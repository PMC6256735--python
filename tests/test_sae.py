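"""Sparse autoencoder: objective decomposition, gradients, training."""

import numpy as np
import numpy.testing as npt
import pytest

from nsca.io_core import FeatureMatrix, InvariantError
from nsca.sae import (AeLayer, SaeHyper, ae_gradient, ae_objective, decode,
                      encode, fit_stack, init_layer, load_stack, reduce,
                      save_stack, train_layer)


def zero_layer(n_x, n_h):
    return AeLayer(W=np.zeros((n_h, n_x)), W_dec=np.zeros((n_x, n_h)),
                   b=np.zeros(n_h), a_bias=np.zeros(n_x))


class TestEncodeDecode:
    def test_zero_weights_give_half(self):
        layer = zero_layer(3, 2)
        npt.assert_allclose(encode(np.zeros(3), layer), [0.5, 0.5])
        npt.assert_allclose(decode(np.zeros(2), layer), [0.5, 0.5, 0.5])

    def test_large_preactivation_saturates_without_overflow(self):
        layer = zero_layer(1, 1)
        layer.W[:] = 1000.0
        h = encode(np.array([1.0]), layer)
        assert 0.0 < h[0] <= 1.0 and np.isfinite(h[0])
        layer.W[:] = -1000.0
        h = encode(np.array([1.0]), layer)
        assert np.isfinite(h[0]) and h[0] >= 0.0

    def test_length_mismatch_rejected(self):
        layer = zero_layer(3, 2)
        with pytest.raises(InvariantError):
            encode(np.zeros(4), layer)
        with pytest.raises(InvariantError):
            decode(np.zeros(3), layer)

    def test_reconstruction_has_input_shape(self, rng):
        layer = init_layer(5, 3, seed=1)
        x = rng.uniform(size=5)
        assert decode(encode(x, layer), layer).shape == x.shape


class TestObjective:
    def test_zero_at_perfect_reconstruction_without_penalties(self):
        # the identity-ish fixed point: sigmoid(large logit) reproduces 0/1
        layer = zero_layer(2, 2)
        layer.a_bias[:] = 0.0  # x' = 0.5 everywhere
        X = np.full((4, 2), 0.5)
        total, mse, wterm, sterm = ae_objective(
            X, layer, weight_decay=0.0, sparsity_weight=0.0,
            sparsity_target=0.5)
        assert total == mse == 0.0 and wterm == 0.0 and sterm == 0.0

    def test_kl_term_zero_when_activation_hits_target(self):
        layer = zero_layer(2, 3)  # rho_hat = 0.5 exactly
        X = np.full((5, 2), 0.3)
        *_, sterm = ae_objective(X, layer, 0.0, 2.0, 0.5)
        assert sterm == pytest.approx(0.0, abs=1e-12)

    def test_weight_decay_adds_exactly_lambda_norm(self, rng):
        layer = init_layer(4, 3, seed=2)
        X = rng.uniform(0.2, 0.8, size=(6, 4))
        j0 = ae_objective(X, layer, 0.0, 0.0, 0.1)[0]
        j1, _, wterm, _ = ae_objective(X, layer, 0.5, 0.0, 0.1)
        npt.assert_allclose(j1 - j0, 0.5 * np.sum(layer.W_dec ** 2))
        npt.assert_allclose(wterm, 0.5 * np.sum(layer.W_dec ** 2))

    def test_terms_nonnegative_and_additive(self, rng):
        layer = init_layer(4, 2, seed=3)
        X = rng.uniform(0.1, 0.9, size=(5, 4))
        total, mse, wterm, sterm = ae_objective(X, layer, 1e-3, 0.2, 0.05)
        assert min(mse, wterm, sterm) >= 0.0
        npt.assert_allclose(total, mse + wterm + sterm)

    def test_bad_sparsity_target_rejected(self, rng):
        layer = init_layer(2, 2, seed=0)
        with pytest.raises(InvariantError):
            ae_objective(np.ones((2, 2)) * 0.5, layer, 0.0, 0.1, 1.5)


class TestGradient:
    @pytest.mark.parametrize("decay_encode", [False, True])
    def test_analytic_matches_central_differences(self, decay_encode, rng):
        X = rng.uniform(0.1, 0.9, size=(5, 4))
        layer = init_layer(4, 3, seed=7)
        args = (1e-3, 0.2, 0.1, decay_encode)
        grads = ae_gradient(X, layer, *args)
        eps = 1e-6
        for analytic, arr in zip(grads, (layer.W, layer.W_dec, layer.b,
                                         layer.a_bias)):
            numeric = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + eps
                jp = ae_objective(X, layer, *args)[0]
                arr[i] = orig - eps
                jm = ae_objective(X, layer, *args)[0]
                arr[i] = orig
                numeric[i] = (jp - jm) / (2 * eps)
            rel = np.max(np.abs(analytic - numeric)
                         / np.maximum(np.abs(numeric), 1e-8))
            assert rel < 1e-5


class TestTraining:
    def test_loss_decreases_on_random_data(self, rng):
        X = rng.uniform(size=(50, 8))
        layer, losses = train_layer(X, 4, SaeHyper(epochs=200), seed=0)
        assert losses[-1] < losses[0]

    def test_loss_non_increasing_at_default_rate(self, rng):
        X = rng.uniform(size=(40, 6))
        _, losses = train_layer(X, 3, SaeHyper(epochs=300), seed=0)
        diffs = np.diff(losses)
        assert np.all(diffs <= 1e-12)

    def test_deterministic_given_seed(self, rng):
        X = rng.uniform(size=(20, 5))
        l1, _ = train_layer(X, 3, SaeHyper(epochs=50), seed=4)
        l2, _ = train_layer(X, 3, SaeHyper(epochs=50), seed=4)
        npt.assert_array_equal(l1.W, l2.W)
        npt.assert_array_equal(l1.a_bias, l2.a_bias)

    def test_overcomplete_hidden_layer_allowed(self, rng):
        X = rng.uniform(size=(10, 3))
        layer, _ = train_layer(X, 5, SaeHyper(epochs=10), seed=0)
        assert layer.n_h == 5

    def test_divergence_names_epoch(self, rng):
        X = rng.uniform(size=(10, 3))
        with pytest.raises(InvariantError, match="epoch"):
            train_layer(X, 2, SaeHyper(epochs=500, learning_rate=1e6), seed=0)


class TestStack:
    def test_reduced_dimension_and_range(self, rng):
        X = rng.uniform(size=(30, 12))
        fm = FeatureMatrix(values=X, feature_names=[f"f{i}" for i in range(12)],
                           epoch_ids=[f"e{i}" for i in range(30)])
        stack = fit_stack(fm, h1=6, h2=3, hyper=SaeHyper(epochs=30), seed=0)
        red = reduce(fm, stack)
        assert red.values.shape == (30, 3)
        assert np.all((red.values > 0) & (red.values < 1))

    def test_identical_rows_reduce_identically(self, rng):
        X = np.tile(rng.uniform(size=12), (4, 1))
        fm = FeatureMatrix(values=X, feature_names=[f"f{i}" for i in range(12)],
                           epoch_ids=[f"e{i}" for i in range(4)])
        stack = fit_stack(fm, 5, 2, SaeHyper(epochs=10), seed=0)
        red = reduce(fm, stack)
        npt.assert_array_equal(red.values[0], red.values[3])

    def test_class_centroids_distinct_after_reduction(self, small_features):
        from nsca.io_core import normalize_features
        from nsca.sae import reduce_rows
        norm = normalize_features(small_features)
        stack = fit_stack(norm, 16, 8, SaeHyper(epochs=100), seed=0)
        Z = reduce_rows(norm.values, stack)
        cents = np.array([Z[norm.labels == c].mean(axis=0)
                          for c in (1, 2, 3, 4)])
        from scipy.spatial.distance import pdist
        assert np.all(pdist(cents) > 0)

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.uniform(size=(10, 4))
        fm = FeatureMatrix(values=X, feature_names=list("abcd"),
                           epoch_ids=[str(i) for i in range(10)])
        stack = fit_stack(fm, 3, 2, SaeHyper(epochs=5), seed=0)
        bad = FeatureMatrix(values=rng.uniform(size=(2, 5)),
                            feature_names=list("abcde"), epoch_ids=["x", "y"])
        with pytest.raises(InvariantError):
            reduce(bad, stack)

    def test_save_load_round_trip(self, rng, tmp_path):
        X = rng.uniform(size=(10, 4))
        stack = fit_stack(X, 3, 2, SaeHyper(epochs=5), seed=0)
        save_stack(stack, tmp_path / "s")
        stack2 = load_stack(tmp_path / "s")
        npt.assert_array_equal(stack.layer1.W, stack2.layer1.W)
        npt.assert_array_equal(stack.layer2.W_dec, stack2.layer2.W_dec)
        assert stack2.hyper == stack.hyper
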