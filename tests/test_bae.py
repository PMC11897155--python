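"""Autoencoder engine: decoder map, pseudo-responses, training loop."""

import numpy as np
import pytest

from boostae import (BoostingConfig, DecoderParams, TrainConfig, decode, encode,
                     latent_pseudo_responses, reconstruction_loss, train_bae)
from boostae.bae import (_gradients, encoder_epoch_update, init_decoder,
                         register_activation)
from conftest import rng_standardized


def small_decoder(p, d, seed=0):
    return init_decoder(p, d, np.random.default_rng(seed))


class TestDecode:
    def test_all_zero_parameters_give_constant_output(self):
        params = DecoderParams(np.zeros((3, 2)), np.zeros(3), np.zeros((3, 3)), np.zeros(3))
        out = decode(np.random.default_rng(0).normal(size=(5, 2)), params)
        np.testing.assert_array_equal(out, np.zeros((5, 3)))

    def test_scalar_identity_weights(self):
        params = DecoderParams(np.ones((1, 1)), np.zeros(1), np.ones((1, 1)), np.zeros(1))
        assert decode(np.array([[0.0]]), params)[0, 0] == 0.0
        np.testing.assert_allclose(decode(np.array([[1.0]]), params)[0, 0],
                                   np.tanh(1.0), atol=1e-5)

    def test_shape_mismatch_rejected(self):
        params = small_decoder(4, 2)
        with pytest.raises(ValueError, match="latent dimension"):
            decode(np.zeros((3, 3)), params)


class TestReconstructionLoss:
    @pytest.mark.parametrize("x, xhat, expected", [
        (np.ones((3, 2)), np.ones((3, 2)), 0.0),
        (np.array([[1.0, 1.0]]), np.array([[0.0, 0.0]]), 1.0),
        (np.array([[1.0], [-1.0]]), np.zeros((2, 1)), 1.0),
    ])
    def test_values(self, x, xhat, expected):
        assert reconstruction_loss(x, xhat) == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestPseudoResponses:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        n, p, d = 6, 5, 2
        X = rng_standardized(rng, n, p)
        B = rng.normal(size=(p, d)) * 0.3
        params = small_decoder(p, d, seed=4)
        Z = X @ B
        _, dZ = _gradients(X, Z, params)
        eps = 1e-6
        fd = np.zeros_like(Z)
        for i in range(n):
            for l in range(d):
                Zp, Zm = Z.copy(), Z.copy()
                Zp[i, l] += eps
                Zm[i, l] -= eps
                fd[i, l] = (reconstruction_loss(X, decode(Zp, params))
                            - reconstruction_loss(X, decode(Zm, params))) / (2 * eps)
        np.testing.assert_allclose(dZ, fd, rtol=1e-6, atol=1e-9)

    def test_identity_like_decoder_hand_case(self):
        # W1=W2=1, b=0, X=[1;-1], B=0: raw negative gradient prop. to x,
        # standardized to [1/sqrt(2), -1/sqrt(2)]
        params = DecoderParams(np.ones((1, 1)), np.zeros(1), np.ones((1, 1)), np.zeros(1))
        X = np.array([[1.0], [-1.0]])
        G_hat, skipped = latent_pseudo_responses(X, np.zeros((1, 1)), params)
        assert skipped == []
        np.testing.assert_allclose(G_hat[:, 0], [1 / np.sqrt(2), -1 / np.sqrt(2)], atol=1e-7)

    def test_perfect_reconstruction_skips_dimension(self):
        # W2 = 0 makes the output constant b2 and the latent gradient exactly 0
        p, d = 3, 1
        params = DecoderParams(np.ones((p, d)), np.zeros(p), np.zeros((p, p)), np.zeros(p))
        X = rng_standardized(np.random.default_rng(0), 5, p)
        G_hat, skipped = latent_pseudo_responses(X, np.zeros((p, d)), params)
        assert skipped == [0]
        assert np.isnan(G_hat[:, 0]).all()

    def test_columns_standardized(self):
        rng = np.random.default_rng(9)
        X = rng_standardized(rng, 12, 6)
        B = rng.normal(size=(6, 3)) * 0.2
        G_hat, skipped = latent_pseudo_responses(X, B, small_decoder(6, 3, 1))
        assert skipped == []
        np.testing.assert_allclose(G_hat.mean(0), 0, atol=1e-10)
        np.testing.assert_allclose(G_hat.std(0, ddof=1), 1, atol=1e-8)

    def test_descent_direction(self):
        """A small step of Z along the raw negative gradient must not increase
        the batch loss."""
        rng = np.random.default_rng(3)
        X = rng_standardized(rng, 10, 7)
        B = rng.normal(size=(7, 2)) * 0.1
        params = small_decoder(7, 2, seed=8)
        Z = X @ B
        _, dZ = _gradients(X, Z, params)
        before = reconstruction_loss(X, decode(Z, params))
        after = reconstruction_loss(X, decode(Z - 1e-4 * dZ, params))
        assert after <= before


class TestEncoderEpochUpdate:
    def test_first_epoch_selects_one_gene_per_dimension(self):
        rng = np.random.default_rng(1)
        X = rng_standardized(rng, 20, 8)
        d = 3
        B = np.zeros((8, d))
        encoder_epoch_update(X, B, small_decoder(8, d, 2), BoostingConfig(0.05, 1))
        assert np.count_nonzero(B) == d
        assert all(np.count_nonzero(B[:, l]) == 1 for l in range(d))

    def test_zero_gradient_leaves_encoder_unchanged(self):
        p, d = 4, 2
        params = DecoderParams(np.ones((p, d)), np.zeros(p), np.zeros((p, p)), np.zeros(p))
        X = rng_standardized(np.random.default_rng(5), 9, p)
        B = np.zeros((p, d))
        records = []
        encoder_epoch_update(X, B, params, BoostingConfig(0.05, 1), records=records)
        np.testing.assert_array_equal(B, 0.0)
        assert all("skipped" in r for r in records)

    def test_selected_gene_maximizes_squared_inner_product(self, stairlike_small):
        X, _, _ = stairlike_small
        d = 2
        B = np.zeros((X.shape[1], d))
        params = small_decoder(X.shape[1], d, 6)
        G_hat, _ = latent_pseudo_responses(X, B, params)
        expected = int(np.argmax((X.T @ G_hat[:, 0]) ** 2))
        records = []
        encoder_epoch_update(X, B, params, BoostingConfig(0.05, 1), records=records)
        assert records[0]["gene"] == expected


class TestTrainBae:
    def test_zero_epochs_leaves_zero_encoder(self):
        X = rng_standardized(np.random.default_rng(0), 10, 6)
        res = train_bae(X, TrainConfig(latent_dim=2, n_epochs=0, seed=1))
        np.testing.assert_array_equal(res.B, 0.0)
        assert res.history == []

    def test_invalid_configs_rejected(self):
        X = rng_standardized(np.random.default_rng(0), 10, 6)
        with pytest.raises(ValueError):
            TrainConfig(latent_dim=2, n_epochs=5, mode="bogus")
        with pytest.raises(ValueError):
            train_bae(X, TrainConfig(latent_dim=6, n_epochs=1))  # d >= p
        with pytest.raises(ValueError):
            train_bae(X, TrainConfig(latent_dim=2, n_epochs=1, batch_size=99))

    def test_activation_with_vanishing_derivative_rejected(self):
        with pytest.raises(ValueError, match="zero derivative"):
            register_activation("relu", lambda a: np.maximum(a, 0),
                                lambda a: (np.asarray(a) > 0).astype(float))

    @pytest.mark.parametrize("mode", ["alternating", "jointLoss"])
    def test_sparsity_bounds_full_batch(self, mode, stairlike_small):
        X, _, design = stairlike_small
        d, N = design.n_groups, 8
        res = train_bae(X, TrainConfig(latent_dim=d, n_epochs=N, mode=mode, seed=2))
        nnz = np.count_nonzero(res.B)
        assert d <= nnz <= d * N

    def test_never_selected_coefficients_are_exact_zero(self, stairlike_small):
        X, _, _ = stairlike_small
        res = train_bae(X, TrainConfig(latent_dim=3, n_epochs=5, seed=0))
        touched = {(r["gene"], r["dimension"]) for h in res.history
                   for r in h["selections"] if r["gene"] >= 0}
        mask = np.zeros_like(res.B, dtype=bool)
        for g, l in touched:
            mask[g, l] = True
        assert np.all(res.B[~mask] == 0.0)

    def test_training_reduces_loss_on_stairlike(self, stairlike_small):
        X, _, design = stairlike_small
        res = train_bae(X, TrainConfig(latent_dim=design.n_groups, n_epochs=15, seed=4))
        assert res.history[-1]["loss"] < res.history[0]["loss"]

    @pytest.mark.parametrize("mode", ["alternating", "jointLoss"])
    def test_identical_seed_gives_bitwise_identical_selection_history(self, mode,
                                                                      stairlike_small):
        X, _, _ = stairlike_small
        cfg = TrainConfig(latent_dim=4, n_epochs=6, mode=mode, batch_size=100, seed=123)
        a = train_bae(X, cfg)
        b = train_bae(X, cfg)
        sel_a = [(r["dimension"], r["gene"], r["coefficient"])
                 for h in a.history for r in h["selections"]]
        sel_b = [(r["dimension"], r["gene"], r["coefficient"])
                 for h in b.history for r in h["selections"]]
        assert sel_a == sel_b
        np.testing.assert_array_equal(a.B, b.B)


class TestEncode:
    def test_zero_encoder_gives_zero_representation(self):
        assert not encode(np.ones((4, 3)), np.zeros((3, 2))).any()

    def test_one_hot_encoder_extracts_scaled_gene(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        B = np.zeros((3, 1))
        B[1, 0] = 2.5
        np.testing.assert_allclose(encode(X, B)[:, 0], 2.5 * X[:, 1])

    def test_matches_matrix_product(self):
        rng = np.random.default_rng(7)
        X, B = rng.normal(size=(5, 3)), rng.normal(size=(3, 2))
        np.testing.assert_array_equal(encode(X, B), X @ B)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            encode(np.ones((4, 3)), np.zeros((2, 2)))
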