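"""RBM conditionals against exhaustive enumeration, CD-1 updates, training."""

import itertools

import numpy as np
import pytest

from gainfields.rbm import (RBM, cd1_gradients, energy, hidden_probabilities,
                            visible_probabilities)


def enumerate_conditional(W, b, c, v):
    """Oracle: P(h_j=1|v) from the Boltzmann joint by explicit enumeration."""
    H = W.shape[0]
    probs = np.zeros(H)
    Z = 0.0
    for bits in itertools.product([0, 1], repeat=H):
        h = np.array(bits, dtype=float)
        w = np.exp(-energy(W, b, c, v, h))
        Z += w
        probs += w * h
    return probs / Z


class TestConditionals:
    def test_zero_model_gives_half(self):
        W = np.zeros((3, 4))
        assert np.allclose(hidden_probabilities(W, np.zeros(3),
                                                np.ones(4)), 0.5)
        assert np.allclose(visible_probabilities(W, np.zeros(4),
                                                 np.ones(3)), 0.5)

    @pytest.mark.parametrize("n_vis,n_hid,seed", [(2, 2, 0), (4, 3, 1),
                                                  (6, 4, 2)])
    def test_against_enumeration(self, n_vis, n_hid, seed):
        rng = np.random.default_rng(seed)
        W = rng.normal(size=(n_hid, n_vis))
        b = rng.normal(size=n_vis)
        c = rng.normal(size=n_hid)
        for bits in itertools.product([0, 1], repeat=n_vis):
            v = np.array(bits, dtype=float)
            assert np.allclose(hidden_probabilities(W, c, v),
                               enumerate_conditional(W, b, c, v),
                               atol=1e-10)
        # and symmetrically for the visible layer
        for bits in itertools.product([0, 1], repeat=n_hid):
            h = np.array(bits, dtype=float)
            oracle = enumerate_conditional(W.T, c, b, h)
            assert np.allclose(visible_probabilities(W, b, h), oracle,
                               atol=1e-10)

    def test_permutation_symmetry(self):
        rng = np.random.default_rng(3)
        W = rng.normal(size=(3, 5))
        c = rng.normal(size=3)
        v = rng.random(5)
        perm = rng.permutation(5)
        assert np.allclose(hidden_probabilities(W, c, v),
                           hidden_probabilities(W[:, perm], c, v[perm]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            hidden_probabilities(np.zeros((2, 3)), np.zeros(2), np.ones(4))


class TestEnergy:
    def test_linearity_under_parameter_perturbation(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(3, 4)); b = rng.normal(size=4)
        c = rng.normal(size=3)
        v = rng.random(4); h = rng.integers(0, 2, 3).astype(float)
        dW = rng.normal(size=(3, 4)); db = rng.normal(size=4)
        dc = rng.normal(size=3)
        delta = energy(W + dW, b + db, c + dc, v, h) - energy(W, b, c, v, h)
        assert delta == pytest.approx(-db @ v - dc @ h - h @ dW @ v)


class TestCD1:
    def test_fixed_point_without_sampling(self):
        # if the mean-field reconstruction reproduces the batch, the
        # positive and negative statistics coincide and the update vanishes
        rng = np.random.default_rng(0)
        W = rng.normal(size=(3, 4)); c = rng.normal(size=3)
        v = rng.random((2, 4))
        h = hidden_probabilities(W, c, v)
        # craft visible biases huge so reconstruction saturates to v==1
        v1 = np.ones((2, 4))
        b = 500 * np.ones(4)
        dW, db, dc, _, v_neg = cd1_gradients(W, b, c, v1,
                                             sample_hidden=False)
        assert np.allclose(v_neg, 1.0, atol=1e-12)
        assert np.allclose(dW, 0, atol=1e-9)
        assert np.allclose(db, 0, atol=1e-9)
        assert np.allclose(dc, 0, atol=1e-9)

    def test_hand_computed_toy_update(self):
        # 3 visible / 2 hidden, deterministic hidden "sample" forced by
        # saturating hidden biases; recompute the update rule scalar-wise
        W = np.array([[1.0, -1.0, 0.5], [0.0, 2.0, -1.0]])
        b = np.array([0.1, -0.2, 0.3])
        c = np.array([500.0, -500.0])  # h = (1, 0) deterministically
        v = np.array([[1.0, 0.0, 1.0]])
        dW, db, dc, h_pos, v_neg = cd1_gradients(
            W, b, c, v, rng=np.random.default_rng(0))
        h_prob = 1 / (1 + np.exp(-(c + W @ v[0])))
        v_neg_hand = 1 / (1 + np.exp(-(b + W[0])))  # h_sample = (1, 0)
        h_neg_hand = 1 / (1 + np.exp(-(c + W @ v_neg_hand)))
        assert np.allclose(h_pos[0], h_prob)
        assert np.allclose(v_neg[0], v_neg_hand)
        assert np.allclose(dW, np.outer(h_prob, v[0])
                           - np.outer(h_neg_hand, v_neg_hand))
        assert np.allclose(db, v[0] - v_neg_hand)
        assert np.allclose(dc, h_prob - h_neg_hand)

    def test_expected_update_vanishes_at_model_distribution(self):
        # when the data comes from the model itself, the CD-1 update is
        # unbiased around zero (Monte-Carlo check on a tiny model)
        rng = np.random.default_rng(42)
        W = 0.5 * rng.normal(size=(2, 3))
        b = 0.1 * rng.normal(size=3)
        c = 0.1 * rng.normal(size=2)
        # exact model marginal over v by enumeration
        states = [np.array(s, dtype=float)
                  for s in itertools.product([0, 1], repeat=3)]
        weights = []
        for v in states:
            z = sum(np.exp(-energy(W, b, c, v, np.array(h, dtype=float)))
                    for h in itertools.product([0, 1], repeat=2))
            weights.append(z)
        pv = np.array(weights) / sum(weights)
        draws = rng.choice(len(states), size=4000, p=pv)
        v_batch = np.array(states)[draws]
        dW, _, _, _, _ = cd1_gradients(W, b, c, v_batch, rng=rng)
        assert np.abs(dW).max() < 0.05


class TestTraining:
    def test_seeded_determinism(self, tiny_dataset):
        X = tiny_dataset.inputs("train")[:100]
        a = RBM(n_hidden=10, n_epochs=3, random_state=5).fit(X)
        b = RBM(n_hidden=10, n_epochs=3, random_state=5).fit(X)
        assert np.array_equal(a.weights_, b.weights_)

    def test_reconstruction_error_decreases(self, tiny_dataset):
        X = tiny_dataset.inputs("train")[:200]
        m = RBM(n_hidden=30, n_epochs=15, random_state=0).fit(X)
        assert m.reconstruction_errors_[-1] < m.reconstruction_errors_[0]

    def test_sparsity_direction_and_enforcement(self, tiny_dataset):
        X = tiny_dataset.inputs("train")
        m = RBM(n_hidden=50, n_epochs=20, sparsity_target=0.05,
                random_state=0).fit(X)
        assert m.mean_hidden_activation_ <= 0.05 + 0.01
        free = RBM(n_hidden=50, n_epochs=20, sparsity_target=None,
                   random_state=0).fit(X)
        assert free.mean_hidden_activation_ > m.mean_hidden_activation_

    def test_transform_matches_conditional(self, tiny_dataset):
        X = tiny_dataset.inputs("train")[:50]
        m = RBM(n_hidden=10, n_epochs=2, random_state=0).fit(X)
        assert np.allclose(m.transform(X),
                           hidden_probabilities(m.weights_, m.hidden_bias_,
                                                X))
        # zero input gives sigmoid of the hidden bias
        z = m.transform(np.zeros((1, X.shape[1])))
        assert np.allclose(z, 1 / (1 + np.exp(-m.hidden_bias_)))

    def test_roundtrip_serialization(self, tiny_dataset, tmp_path):
        X = tiny_dataset.inputs("train")[:50]
        m = RBM(n_hidden=8, n_epochs=2, sparsity_target=0.1,
                random_state=0).fit(X)
        path = tmp_path / "rbm.h5"
        m.save(path)
        back = RBM.load(path)
        assert np.array_equal(back.weights_, m.weights_)
        assert back.get_params() == m.get_params()


class TestApplySparsity:
    def test_no_change_at_target(self):
        from gainfields.rbm import apply_sparsity
        c = np.array([0.3, -0.2])
        out = apply_sparsity(c, np.array([0.05, 0.05]), 0.05, 1.0)
        assert np.allclose(out, c)

    def test_direction_and_validation(self):
        from gainfields.rbm import apply_sparsity
        c = np.zeros(2)
        out = apply_sparsity(c, np.array([0.2, 0.01]), 0.05, 1.0)
        assert out[0] < 0 < out[1]  # overactive down, underactive up
        with pytest.raises(ValueError, match="0, 1"):
            apply_sparsity(c, np.array([1.2, 0.0]), 0.05, 1.0)
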