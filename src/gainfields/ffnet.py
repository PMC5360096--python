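"""Supervised feed-forward network mapping sensory input to the motor map.

One sigmoid hidden layer and a sigmoid output layer trained by full-batch
gradient descent on the mean (per pattern) summed squared output error --
the classic supervised baseline for sensorimotor transformation, in the
Gaussian output format.  No sparsity constraint is applied.
"""

from __future__ import annotations

import h5py
import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["FeedForwardNetwork", "ff_forward", "train_ffnet",
           "ff_hidden_activations"]


def ff_forward(W1, W2, c, b, v):
    """Forward pass; returns ``(h, out)`` for a vector or batch (rows)."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != W1.shape[1]:
        raise ValueError(f"input length {v.shape[-1]} does not match the "
                         f"network ({W1.shape[1]})")
    h = expit(v @ W1.T + c)
    out = expit(h @ W2.T + b)
    return h, out


class FeedForwardNetwork(RegressorMixin, BaseEstimator):
    """One-hidden-layer supervised network trained by batch backprop.

    Parameters
    ----------
    n_hidden : int, default 500
    learning_rate : float, default 0.05
    n_epochs : int, default 2500
    random_state : int or None

    Attributes
    ----------
    input_weights_ : ndarray (n_hidden, n_inputs)
    output_weights_ : ndarray (n_outputs, n_hidden)
    hidden_bias_, output_bias_ : ndarray
    loss_curve_ : ndarray (n_epochs,)
        Mean summed squared output error per epoch.
    """

    def __init__(self, n_hidden: int = 500, learning_rate: float = 0.05,
                 n_epochs: int = 2500, random_state: int | None = None,
                 verbose: bool = False):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.random_state = random_state
        self.verbose = verbose

    def fit(self, X, Y) -> "FeedForwardNetwork":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or len(X) != len(Y):
            raise ValueError("X and Y must be aligned 2-d arrays")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        n, n_in = X.shape
        n_out = Y.shape[1]
        rng = np.random.default_rng(self.random_state)
        W1 = rng.normal(0.0, 0.01, size=(self.n_hidden, n_in))
        W2 = rng.normal(0.0, 0.01, size=(n_out, self.n_hidden))
        c = np.zeros(self.n_hidden)
        b = np.zeros(n_out)
        lr = self.learning_rate
        losses = np.empty(self.n_epochs)
        for epoch in range(self.n_epochs):
            h = expit(X @ W1.T + c)
            out = expit(h @ W2.T + b)
            err = out - Y
            losses[epoch] = float((err ** 2).sum() / n)
            d_pre2 = (2.0 / n) * err * out * (1.0 - out)
            gW2 = d_pre2.T @ h
            gb = d_pre2.sum(axis=0)
            d_pre1 = (d_pre2 @ W2) * h * (1.0 - h)
            gW1 = d_pre1.T @ X
            gc = d_pre1.sum(axis=0)
            W1 -= lr * gW1
            W2 -= lr * gW2
            c -= lr * gc
            b -= lr * gb
            if not np.isfinite(W1).all() or not np.isfinite(W2).all():
                raise FloatingPointError(
                    f"feed-forward training diverged at epoch {epoch + 1}; "
                    "lower the learning rate")
            if self.verbose and (epoch + 1) % 100 == 0:
                print(f"[ffnet] epoch {epoch + 1:4d}  "
                      f"loss {losses[epoch]:.5f}")
        self.input_weights_ = W1
        self.output_weights_ = W2
        self.hidden_bias_ = c
        self.output_bias_ = b
        self.loss_curve_ = losses
        self.n_inputs_ = n_in
        self.n_outputs_ = n_out
        return self

    def predict(self, X) -> np.ndarray:
        """Network output maps."""
        check_is_fitted(self, "input_weights_")
        _, out = ff_forward(self.input_weights_, self.output_weights_,
                            self.hidden_bias_, self.output_bias_, X)
        return out

    def transform(self, X) -> np.ndarray:
        """Hidden activations (probe interface shared with the encoders)."""
        check_is_fitted(self, "input_weights_")
        X = np.asarray(X, dtype=float)
        return expit(X @ self.input_weights_.T + self.hidden_bias_)

    def hidden_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """First-layer affine map ``(W, bias)`` behind the hidden sigmoid."""
        check_is_fitted(self, "input_weights_")
        return self.input_weights_, self.hidden_bias_

    # ----- serialization ----------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self, "input_weights_")
        with h5py.File(path, "w") as fh:
            fh.attrs["estimator"] = "FeedForwardNetwork"
            for k, val in self.get_params().items():
                fh.attrs[f"param_{k}"] = "none" if val is None else val
            fh.create_dataset("input_weights", data=self.input_weights_)
            fh.create_dataset("output_weights", data=self.output_weights_)
            fh.create_dataset("hidden_bias", data=self.hidden_bias_)
            fh.create_dataset("output_bias", data=self.output_bias_)
            fh.create_dataset("loss_curve", data=self.loss_curve_)

    @classmethod
    def load(cls, path) -> "FeedForwardNetwork":
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
            model.input_weights_ = fh["input_weights"][...]
            model.output_weights_ = fh["output_weights"][...]
            model.hidden_bias_ = fh["hidden_bias"][...]
            model.output_bias_ = fh["output_bias"][...]
            model.loss_curve_ = fh["loss_curve"][...]
            model.n_inputs_ = model.input_weights_.shape[1]
            model.n_outputs_ = model.output_weights_.shape[0]
        return model

    def log_frame(self):
        import pandas as pd
        check_is_fitted(self, "input_weights_")
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.loss_curve_) + 1),
            "output_error": self.loss_curve_,
        })


def train_ffnet(X, Y, **hyper) -> FeedForwardNetwork:
    """Train a :class:`FeedForwardNetwork`; keywords as in the class."""
    return FeedForwardNetwork(**hyper).fit(X, Y)


def ff_hidden_activations(model: FeedForwardNetwork, X) -> np.ndarray:
    return model.transform(X)
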