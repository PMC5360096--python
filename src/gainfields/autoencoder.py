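"""Single-hidden-layer sparse autoencoder.

A deterministic feed-forward network trained to reconstruct its input in a
separate output layer:

    h     = sigmoid(W1 v + c)
    v_rec = sigmoid(W2 h + b)

with independent (untied) encoder and decoder weights.  The objective is

    E = (1/N) sum_n sum_k (v_nk - v_rec_nk)^2  +  beta * Omega  +  decay

where ``Omega = sum_i KL(p || q_i)`` penalizes, through the
Kullback-Leibler divergence (natural logarithm), the deviation of each
hidden unit's batch-mean activation ``q_i`` from the sparsity target ``p``,
and the decay term is ``wd (||W1||^2 + ||W2||^2) / 2`` on the weights only.

Optimization is full-batch scaled conjugate gradient (with a plain
gradient-descent fallback for debugging).
"""

from __future__ import annotations

import h5py
import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._scg import scg_minimize

__all__ = ["SparseAutoencoder", "forward", "loss_terms", "gradients",
           "train_autoencoder"]

_Q_CLIP = 1e-6  # keeps the KL term finite when a unit saturates early


def forward(W1, W2, c, b, v):
    """Forward pass; returns ``(h, v_rec)`` for a vector or batch (rows)."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != W1.shape[1]:
        raise ValueError(f"input length {v.shape[-1]} does not match the "
                         f"encoder ({W1.shape[1]})")
    h = expit(v @ W1.T + c)
    v_rec = expit(h @ W2.T + b)
    return h, v_rec


def loss_terms(W1, W2, c, b, X, sparsity_target: float,
               sparsity_weight: float, weight_decay: float) -> dict:
    """Loss with its per-term breakdown on a batch.

    Returns a dict with ``reconstruction`` (mean per pattern of the summed
    squared output error), ``sparsity`` (KL penalty, already scaled by
    beta), ``decay`` and ``total``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    h, v_rec = forward(W1, W2, c, b, X)
    recon = float(((X - v_rec) ** 2).sum() / len(X))
    p = sparsity_target
    q = np.clip(h.mean(axis=0), _Q_CLIP, 1.0 - _Q_CLIP)
    kl = float(np.sum(p * np.log(p / q)
                      + (1.0 - p) * np.log((1.0 - p) / (1.0 - q))))
    decay = float(weight_decay * ((W1 ** 2).sum() + (W2 ** 2).sum()) / 2.0)
    total = recon + sparsity_weight * kl + decay
    return {"reconstruction": recon, "sparsity": sparsity_weight * kl,
            "decay": decay, "total": total}


def _loss_and_grad(theta, X, shapes, p, beta, wd):
    """Objective and exact gradient for the flattened parameter vector."""
    W1, W2, c, b = _unpack(theta, shapes)
    n = len(X)
    h = expit(X @ W1.T + c)
    v_rec = expit(h @ W2.T + b)
    err = v_rec - X
    recon = float((err ** 2).sum() / n)
    q = np.clip(h.mean(axis=0), _Q_CLIP, 1.0 - _Q_CLIP)
    kl = float(np.sum(p * np.log(p / q)
                      + (1.0 - p) * np.log((1.0 - p) / (1.0 - q))))
    decay = wd * ((W1 ** 2).sum() + (W2 ** 2).sum()) / 2.0
    f = recon + beta * kl + decay

    d_pre2 = (2.0 / n) * err * v_rec * (1.0 - v_rec)
    gW2 = d_pre2.T @ h + wd * W2
    gb = d_pre2.sum(axis=0)
    dh = d_pre2 @ W2
    # KL reaches h through the batch mean q_i
    dkl_dq = -p / q + (1.0 - p) / (1.0 - q)
    dh = dh + (beta / n) * dkl_dq
    d_pre1 = dh * h * (1.0 - h)
    gW1 = d_pre1.T @ X + wd * W1
    gc = d_pre1.sum(axis=0)
    return f, _pack(gW1, gW2, gc, gb)


def gradients(W1, W2, c, b, X, sparsity_target, sparsity_weight,
              weight_decay):
    """Exact loss gradients on a batch, as ``(gW1, gW2, gc, gb)``."""
    theta = _pack(np.asarray(W1, float), np.asarray(W2, float),
                  np.asarray(c, float), np.asarray(b, float))
    _, g = _loss_and_grad(theta, np.atleast_2d(np.asarray(X, float)),
                          (np.shape(W1)[0], np.shape(W1)[1]),
                          sparsity_target, sparsity_weight, weight_decay)
    return _unpack(g, (np.shape(W1)[0], np.shape(W1)[1]))


def _pack(W1, W2, c, b):
    return np.concatenate([W1.ravel(), W2.ravel(), c, b])


def _unpack(theta, shapes):
    (h, v) = shapes
    i = 0
    W1 = theta[i:i + h * v].reshape(h, v); i += h * v
    W2 = theta[i:i + v * h].reshape(v, h); i += v * h
    c = theta[i:i + h]; i += h
    b = theta[i:i + v]
    return W1, W2, c, b


class SparseAutoencoder(TransformerMixin, BaseEstimator):
    """Sparse autoencoder trained by full-batch scaled conjugate gradient.

    Parameters
    ----------
    n_hidden : int, default 400
    sparsity_target : float, default 0.05
        Target mean activation ``p`` of each hidden unit.
    sparsity_weight : float, default 3.0
        Weight ``beta`` of the KL penalty; 0 disables it.
    weight_decay : float, default 2e-4
    n_epochs : int, default 150
        Optimizer iterations (one full batch each).
    optimizer : {"scg", "gd"}, default "scg"
        Plain gradient descent (``learning_rate``) is a debugging fallback.
    learning_rate : float, default 0.1
        Used only by the ``gd`` optimizer.
    random_state : int or None

    Attributes
    ----------
    encoder_weights_ : ndarray (n_hidden, n_visible)
    decoder_weights_ : ndarray (n_visible, n_hidden)
    hidden_bias_, output_bias_ : ndarray
    loss_curve_ : ndarray (n_epochs,)
        Accepted total loss per iteration (non-increasing for SCG).
    mean_hidden_activation_ : float
    """

    def __init__(self, n_hidden: int = 400, sparsity_target: float = 0.05,
                 sparsity_weight: float = 3.0, weight_decay: float = 2e-4,
                 n_epochs: int = 150, optimizer: str = "scg",
                 learning_rate: float = 0.1,
                 random_state: int | None = None, verbose: bool = False):
        self.n_hidden = n_hidden
        self.sparsity_target = sparsity_target
        self.sparsity_weight = sparsity_weight
        self.weight_decay = weight_decay
        self.n_epochs = n_epochs
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.verbose = verbose

    def fit(self, X, y=None) -> "SparseAutoencoder":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (patterns x visible units)")
        if not (0.0 < self.sparsity_target < 1.0):
            raise ValueError("sparsity_target must lie in (0, 1)")
        if self.sparsity_weight < 0:
            raise ValueError("sparsity_weight must be non-negative")
        n_vis = X.shape[1]
        shapes = (self.n_hidden, n_vis)
        rng = np.random.default_rng(self.random_state)
        theta0 = _pack(
            rng.normal(0.0, 0.01, size=(self.n_hidden, n_vis)),
            rng.normal(0.0, 0.01, size=(n_vis, self.n_hidden)),
            np.zeros(self.n_hidden), np.zeros(n_vis))

        def fun(theta):
            return _loss_and_grad(theta, X, shapes, self.sparsity_target,
                                  self.sparsity_weight, self.weight_decay)

        if self.optimizer == "scg":
            callback = None
            if self.verbose:
                def callback(k, f):
                    print(f"[autoencoder] iter {k + 1:3d}  loss {f:.5f}")
            theta, trace = scg_minimize(fun, theta0, self.n_epochs, callback)
        elif self.optimizer == "gd":
            theta = theta0
            trace = np.empty(self.n_epochs)
            for k in range(self.n_epochs):
                f, g = fun(theta)
                theta = theta - self.learning_rate * g
                trace[k] = f
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if not np.isfinite(theta).all():
            raise FloatingPointError("autoencoder training diverged")
        W1, W2, c, b = _unpack(theta, shapes)
        self.encoder_weights_ = W1
        self.decoder_weights_ = W2
        self.hidden_bias_ = c
        self.output_bias_ = b
        self.loss_curve_ = trace
        self.n_visible_ = n_vis
        h = self.transform(X)
        self.mean_hidden_activation_ = float(h.mean())
        self.loss_breakdown_ = loss_terms(
            W1, W2, c, b, X, self.sparsity_target, self.sparsity_weight,
            self.weight_decay)
        return self

    def transform(self, X) -> np.ndarray:
        """Hidden activations (the representation analysed downstream)."""
        check_is_fitted(self, "encoder_weights_")
        X = np.asarray(X, dtype=float)
        return expit(X @ self.encoder_weights_.T + self.hidden_bias_)

    def reconstruct(self, X) -> np.ndarray:
        check_is_fitted(self, "encoder_weights_")
        _, v_rec = forward(self.encoder_weights_, self.decoder_weights_,
                           self.hidden_bias_, self.output_bias_, X)
        return v_rec

    def hidden_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """First-layer affine map ``(W, bias)`` behind the hidden sigmoid."""
        check_is_fitted(self, "encoder_weights_")
        return self.encoder_weights_, self.hidden_bias_

    # ----- serialization ----------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self, "encoder_weights_")
        with h5py.File(path, "w") as fh:
            fh.attrs["estimator"] = "SparseAutoencoder"
            for k, val in self.get_params().items():
                fh.attrs[f"param_{k}"] = "none" if val is None else val
            fh.create_dataset("encoder_weights", data=self.encoder_weights_)
            fh.create_dataset("decoder_weights", data=self.decoder_weights_)
            fh.create_dataset("hidden_bias", data=self.hidden_bias_)
            fh.create_dataset("output_bias", data=self.output_bias_)
            fh.create_dataset("loss_curve", data=self.loss_curve_)

    @classmethod
    def load(cls, path) -> "SparseAutoencoder":
        with h5py.File(path, "r") as fh:
            params = {k[6:]: (None if isinstance(v, str) and v == "none"
                              else v)
                      for k, v in fh.attrs.items() if k.startswith("param_")}
            params["n_hidden"] = int(params["n_hidden"])
            params["n_epochs"] = int(params["n_epochs"])
            if params.get("random_state") is not None:
                params["random_state"] = int(params["random_state"])
            params["verbose"] = bool(params["verbose"])
            model = cls(**params)
            model.encoder_weights_ = fh["encoder_weights"][...]
            model.decoder_weights_ = fh["decoder_weights"][...]
            model.hidden_bias_ = fh["hidden_bias"][...]
            model.output_bias_ = fh["output_bias"][...]
            model.loss_curve_ = fh["loss_curve"][...]
            model.n_visible_ = model.encoder_weights_.shape[1]
        return model

    def log_frame(self):
        import pandas as pd
        check_is_fitted(self, "encoder_weights_")
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.loss_curve_) + 1),
            "total_loss": self.loss_curve_,
        })


def train_autoencoder(X, **hyper) -> SparseAutoencoder:
    """Train a :class:`SparseAutoencoder`; keywords as in the class."""
    return SparseAutoencoder(**hyper).fit(X)
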