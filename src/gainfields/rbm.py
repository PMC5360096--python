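"""Restricted Boltzmann Machine trained with 1-step contrastive divergence.

The RBM is a stochastic bipartite network whose energy
``E(v, h) = -b'v - c'h - h'Wv`` defines a Boltzmann joint
``p(v, h) = exp(-E) / Z``.  Because the graph is bipartite the conditionals
factorize and both layers can be sampled in one parallel step:

    P(h_j = 1 | v) = sigmoid(c_j + sum_i w_ji v_i)
    P(v_i = 1 | h) = sigmoid(b_i + sum_j w_ji h_j)

Training follows the CD-1 approximation to the likelihood gradient: the
positive-phase visible/hidden correlations are computed on the data, the
negative-phase correlations after a single Gibbs step.  Real-valued inputs
in [0, 1] are presented directly to sigmoid visible units.

Sparse hidden codes are encouraged by an activity-target mechanism: a
running estimate ``q`` of each hidden unit's mean activation is pushed
toward a desired probability ``p`` by adjusting the hidden biases by
``-lambda (q - p)`` at every weight update.
"""

from __future__ import annotations

import h5py
import numpy as np
from numba import njit
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RBM",
    "energy",
    "hidden_probabilities",
    "visible_probabilities",
    "cd1_gradients",
    "apply_sparsity",
    "train_rbm",
    "hidden_activations",
]


def energy(W: np.ndarray, b: np.ndarray, c: np.ndarray,
           v: np.ndarray, h: np.ndarray) -> float:
    """Energy of a joint configuration, ``-b'v - c'h - h'Wv``."""
    return float(-(b @ v) - (c @ h) - h @ W @ v)


def hidden_probabilities(W, c, v) -> np.ndarray:
    """``P(h = 1 | v)`` for one visible vector or a batch (rows)."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != W.shape[1]:
        raise ValueError(f"visible vector length {v.shape[-1]} does not "
                         f"match the model ({W.shape[1]})")
    return expit(v @ W.T + c)


def visible_probabilities(W, b, h) -> np.ndarray:
    """``P(v = 1 | h)`` for one hidden vector or a batch (rows)."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != W.shape[0]:
        raise ValueError(f"hidden vector length {h.shape[-1]} does not "
                         f"match the model ({W.shape[0]})")
    return expit(h @ W + b)


def cd1_gradients(W, b, c, v_batch, rng=None, sample_hidden: bool = True):
    """Raw CD-1 parameter gradients for one minibatch (before momentum/decay).

    Positive phase: hidden probabilities on the data, with a binary sample
    used to start the negative phase.  Negative phase: mean-field visible
    reconstruction from the sampled hiddens, then hidden probabilities on
    the reconstruction.  Correlation products use probabilities on both
    phases; ``sample_hidden=False`` replaces the binary sample with the
    probabilities (deterministic, used for fixed-point checks).

    Returns ``(dW, db, dc, h_pos, v_neg)`` where the gradients are minibatch
    means and point in the likelihood-ascent direction.
    """
    v_pos = np.atleast_2d(np.asarray(v_batch, dtype=float))
    n = len(v_pos)
    h_pos = hidden_probabilities(W, c, v_pos)
    if sample_hidden:
        if rng is None:
            raise ValueError("rng required when sampling hidden states")
        h_start = (rng.random(h_pos.shape) < h_pos).astype(float)
    else:
        h_start = h_pos
    v_neg = visible_probabilities(W, b, h_start)
    h_neg = hidden_probabilities(W, c, v_neg)
    dW = (h_pos.T @ v_pos - h_neg.T @ v_neg) / n
    db = (v_pos - v_neg).mean(axis=0)
    dc = (h_pos - h_neg).mean(axis=0)
    return dW, db, dc, h_pos, v_neg


def apply_sparsity(hidden_bias, running_q, target, scale):
    """Activity-target bias adjustment: ``c - scale * (q - target)``.

    Pushes each hidden unit's running mean activation ``q`` toward the
    desired probability; applied at every weight update during training.
    Returns the adjusted bias vector (the input is not modified).
    """
    running_q = np.asarray(running_q, dtype=float)
    if np.any(running_q < 0) or np.any(running_q > 1):
        raise ValueError("running activation estimates must lie in [0, 1]")
    return np.asarray(hidden_bias, dtype=float) - scale * (running_q - target)


@njit(cache=True, fastmath=True)
def _cd1_epoch(X, order, uniforms, vis_uniforms, W, b, c, vW, vb, vc, q,
               lr, wd, mom, bs, sp_on, sp_target, sp_scale, sp_decay,
               sample_visible):
    """One CD-1 epoch over shuffled minibatches, updating state in place.

    ``uniforms`` holds the pre-drawn U(0,1) variates for the hidden
    sampling step, aligned with ``order``.  Returns the summed squared
    reconstruction error of the epoch.
    """
    n = len(order)
    sq_err = 0.0
    for s in range(0, n, bs):
        idx = order[s:min(s + bs, n)]
        m = len(idx)
        v_pos = np.empty((m, X.shape[1]))
        for i in range(m):
            v_pos[i] = X[idx[i]]
        h_pos = 1.0 / (1.0 + np.exp(-(np.dot(v_pos, W.T) + c)))
        h_start = (uniforms[s:s + m] < h_pos).astype(np.float64)
        v_neg = 1.0 / (1.0 + np.exp(-(np.dot(h_start, W) + b)))
        if sample_visible:
            v_neg = (vis_uniforms[s:s + m] < v_neg).astype(np.float64)
        h_neg = 1.0 / (1.0 + np.exp(-(np.dot(v_neg, W.T) + c)))
        vW *= mom
        vW += (lr / m) * (np.dot(h_pos.T, v_pos) - np.dot(h_neg.T, v_neg))
        vW -= (lr * wd) * W
        vb *= mom
        vc *= mom
        for i in range(m):
            vb += (lr / m) * (v_pos[i] - v_neg[i])
            vc += (lr / m) * (h_pos[i] - h_neg[i])
        W += vW
        b += vb
        c += vc
        if sp_on:
            q *= sp_decay
            for i in range(m):
                q += ((1.0 - sp_decay) / m) * h_pos[i]
            c -= sp_scale * (q - sp_target)
        for i in range(m):
            for j in range(X.shape[1]):
                d = v_pos[i, j] - v_neg[i, j]
                sq_err += d * d
    return sq_err


class RBM(TransformerMixin, BaseEstimator):
    """Bernoulli-Bernoulli RBM trained with minibatch CD-1.

    Parameters
    ----------
    n_hidden : int, default 400
        Hidden-layer size.
    learning_rate : float, default 0.03
    weight_decay : float, default 2e-4
        L2 penalty on the weights, applied inside the update.
    momentum : float, default 0.9
        Momentum coefficient after the warm-up epochs.
    momentum_initial : float, default 0.5
    initial_momentum_epochs : int, default 5
        Number of warm-up epochs run at ``momentum_initial``.
    batch_size : int, default 4
    n_epochs : int, default 100
    sparsity_target : float or None, default None
        Desired mean hidden activation ``p``; ``None`` disables the
        mechanism.
    sparsity_scale : float, default 1.0
        Scaling factor ``lambda`` of the bias adjustment.
    sparsity_decay : float, default 0.9
        Decay of the exponential moving average estimating ``q``.
    negative_phase : {"mean_field", "sample"}, default "mean_field"
        Whether the negative-phase visible reconstruction uses mean-field
        probabilities or a binary sample.
    random_state : int or None
        Seed for weight initialization, epoch shuffling and Gibbs sampling.

    Attributes
    ----------
    weights_ : ndarray (n_hidden, n_visible)
    visible_bias_ : ndarray (n_visible,)
    hidden_bias_ : ndarray (n_hidden,)
    reconstruction_errors_ : ndarray (n_epochs,)
        Per-epoch mean squared reconstruction error per visible unit.
    mean_hidden_activation_ : float
        Mean hidden probability over the training set after fitting.
    """

    def __init__(self, n_hidden: int = 400, learning_rate: float = 0.03,
                 weight_decay: float = 2e-4, momentum: float = 0.9,
                 momentum_initial: float = 0.5,
                 initial_momentum_epochs: int = 5, batch_size: int = 4,
                 n_epochs: int = 100, sparsity_target: float | None = None,
                 sparsity_scale: float = 1.0, sparsity_decay: float = 0.9,
                 negative_phase: str = "mean_field",
                 random_state: int | None = None, verbose: bool = False):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.momentum = momentum
        self.momentum_initial = momentum_initial
        self.initial_momentum_epochs = initial_momentum_epochs
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.sparsity_target = sparsity_target
        self.sparsity_scale = sparsity_scale
        self.sparsity_decay = sparsity_decay
        self.negative_phase = negative_phase
        self.random_state = random_state
        self.verbose = verbose

    def fit(self, X, y=None) -> "RBM":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (patterns x visible units)")
        p = self.sparsity_target
        if p is not None and not (0.0 < p < 1.0):
            raise ValueError("sparsity_target must lie in (0, 1)")
        n, n_vis = X.shape
        rng = np.random.default_rng(self.random_state)
        W = rng.normal(0.0, 0.01, size=(self.n_hidden, n_vis))
        b = np.zeros(n_vis)
        c = np.zeros(self.n_hidden)
        vW = np.zeros_like(W)
        vb = np.zeros_like(b)
        vc = np.zeros_like(c)
        q = np.full(self.n_hidden, 0.5)
        lr = self.learning_rate
        errors = np.empty(self.n_epochs)
        if self.negative_phase not in ("mean_field", "sample"):
            raise ValueError(f"unknown negative_phase "
                             f"{self.negative_phase!r}")
        sample_visible = self.negative_phase == "sample"
        X = np.ascontiguousarray(X)
        empty = np.empty((0, 0))
        for epoch in range(self.n_epochs):
            mom = (self.momentum_initial
                   if epoch < self.initial_momentum_epochs else self.momentum)
            order = rng.permutation(n)
            uniforms = rng.random((n, self.n_hidden))
            vis_uniforms = rng.random((n, n_vis)) if sample_visible else empty
            sq_err = _cd1_epoch(
                X, order, uniforms, vis_uniforms, W, b, c, vW, vb, vc, q,
                lr, self.weight_decay, mom, self.batch_size,
                p is not None, 0.0 if p is None else p,
                self.sparsity_scale, self.sparsity_decay, sample_visible)
            errors[epoch] = sq_err / (n * n_vis)
            if not np.isfinite(W).all():
                raise FloatingPointError(
                    f"RBM training diverged at epoch {epoch + 1} "
                    "(non-finite weights); reduce the learning rate")
            if self.verbose:
                print(f"[rbm] epoch {epoch + 1:3d}  "
                      f"recon mse {errors[epoch]:.5f}")
        self.weights_ = W
        self.visible_bias_ = b
        self.hidden_bias_ = c
        self.reconstruction_errors_ = errors
        self.n_visible_ = n_vis
        self.mean_hidden_activation_ = float(
            np.mean([hidden_probabilities(W, c, X[i:i + 4096]).mean()
                     for i in range(0, n, 4096)]))
        return self

    def transform(self, X) -> np.ndarray:
        """Deterministic hidden probabilities (the analysed representation)."""
        check_is_fitted(self, "weights_")
        return hidden_probabilities(self.weights_, self.hidden_bias_, X)

    def reconstruct(self, X) -> np.ndarray:
        """Mean-field reconstruction after one up-down pass."""
        check_is_fitted(self, "weights_")
        h = self.transform(X)
        return visible_probabilities(self.weights_, self.visible_bias_, h)

    def hidden_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """First-layer affine map ``(W, bias)`` behind the hidden sigmoid."""
        check_is_fitted(self, "weights_")
        return self.weights_, self.hidden_bias_

    # ----- serialization ----------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self, "weights_")
        with h5py.File(path, "w") as fh:
            fh.attrs["estimator"] = "RBM"
            for k, val in self.get_params().items():
                fh.attrs[f"param_{k}"] = "none" if val is None else val
            fh.create_dataset("weights", data=self.weights_)
            fh.create_dataset("visible_bias", data=self.visible_bias_)
            fh.create_dataset("hidden_bias", data=self.hidden_bias_)
            fh.create_dataset("reconstruction_errors",
                              data=self.reconstruction_errors_)
            fh.attrs["mean_hidden_activation"] = self.mean_hidden_activation_

    @classmethod
    def load(cls, path) -> "RBM":
        with h5py.File(path, "r") as fh:
            params = {k[6:]: (None if isinstance(v, str) and v == "none"
                              else v)
                      for k, v in fh.attrs.items() if k.startswith("param_")}
            for key in ("n_hidden", "batch_size", "n_epochs",
                        "initial_momentum_epochs"):
                params[key] = int(params[key])
            for key in ("random_state",):
                if params.get(key) is not None:
                    params[key] = int(params[key])
            params["verbose"] = bool(params["verbose"])
            model = cls(**params)
            model.weights_ = fh["weights"][...]
            model.visible_bias_ = fh["visible_bias"][...]
            model.hidden_bias_ = fh["hidden_bias"][...]
            model.reconstruction_errors_ = fh["reconstruction_errors"][...]
            model.mean_hidden_activation_ = float(
                fh.attrs["mean_hidden_activation"])
            model.n_visible_ = model.weights_.shape[1]
        return model

    def log_frame(self):
        """Training log as a DataFrame (epoch, reconstruction error)."""
        import pandas as pd
        check_is_fitted(self, "weights_")
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.reconstruction_errors_) + 1),
            "reconstruction_error": self.reconstruction_errors_,
        })


def train_rbm(X, **hyper) -> RBM:
    """Train an :class:`RBM` on an input matrix; keywords as in ``RBM``."""
    return RBM(**hyper).fit(X)


def hidden_activations(model: RBM, X) -> np.ndarray:
    """Deterministic hidden probabilities, row per pattern."""
    return model.transform(X)
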