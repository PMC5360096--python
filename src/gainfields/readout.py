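"""Delta-rule linear read-out and center-of-mass decoding.

The quality of a hidden representation is assessed by how well a *linear*
map from hidden activations to the motor population map can be learned.
The read-out is a linear network (no output squashing) trained with the
Widrow-Hoff delta rule: by default each pattern updates the weights in
turn (the classic sequential LMS recursion, here JIT-compiled), with a
minibatch mean-gradient variant available.  Predicted maps are decoded to
degrees by taking the center of mass (COM) over the motor unit centers,
and a mapping is deemed successful when the mean COM error stays strictly
below 3 deg -- the spacing of the retinotopic tuning centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .stimuli import SpaceConfig


@njit(cache=True, fastmath=True)
def _lms_epoch(X, Y, V, b, order, lr, alpha, decay):
    """One sequential LMS pass.

    The weight matrix is represented as ``alpha * V`` so that the L2 decay
    (a scalar shrink per update) costs O(1) instead of a full-matrix
    multiply per pattern; returns the updated ``alpha``.
    """
    n_out, n_feat = V.shape
    err = np.empty(n_out)
    for t in order:
        x = X[t]
        alpha *= decay
        pred = np.dot(V, x)
        for k in range(n_out):
            err[k] = Y[t, k] - alpha * pred[k] - b[k]
            b[k] += lr * err[k]
        scale = lr / alpha
        for k in range(n_out):
            e = scale * err[k]
            for j in range(n_feat):
                V[k, j] += e * x[j]
    return alpha

__all__ = ["LinearReadout", "ReadoutReport", "decode_com",
           "train_readout", "evaluate_readout"]


def decode_com(output_map, cfg: SpaceConfig | None = None,
               clip_negative: bool = True) -> np.ndarray:
    """Center-of-mass position (degrees) of motor map(s).

    With ``clip_negative`` (default) negative activations are zeroed
    before weighting, which makes the COM well-defined for arbitrary
    maps.  Read-out evaluation decodes *raw* maps instead
    (``clip_negative=False``): the symmetric noise on a trained read-out's
    small negative lobes then cancels in the weighted mean rather than
    accumulating as a positive bias, and the true peak keeps the total
    mass safely positive.  Raises when the (clipped or raw) total mass is
    not positive.
    """
    cfg = cfg or SpaceConfig()
    a = np.atleast_2d(np.asarray(output_map, dtype=float))
    if a.shape[-1] != cfg.motor_grid_size ** 2:
        raise ValueError(f"map length {a.shape[-1]} does not match the "
                         f"motor grid ({cfg.motor_grid_size ** 2})")
    if clip_negative:
        a = np.clip(a, 0.0, None)
    mass = a.sum(axis=1)
    if np.any(mass <= 0.0):
        raise ValueError("COM undefined: map has no positive total mass")
    centers = cfg.grid_centers_2d("motor")
    com = (a @ centers) / mass[:, None]
    return com[0] if np.asarray(output_map).ndim == 1 else com


@dataclass(frozen=True)
class ReadoutReport:
    """Read-out evaluation: map-space RMSE and COM error in degrees."""

    rmse: float
    com_error_mean: float
    com_error_sd: float
    success: bool
    n_patterns: int

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "com_error_mean": self.com_error_mean,
                "com_error_sd": self.com_error_sd, "success": self.success,
                "n_patterns": self.n_patterns}


class LinearReadout(RegressorMixin, BaseEstimator):
    """Linear map from hidden activations to the motor map (delta rule).

    Parameters
    ----------
    learning_rate : float, default 0.07
    n_epochs : int, default 250
    batch_size : int, default 20
        Minibatch size of the ``batch_mean`` update; unused by the
        sequential rule.
    weight_decay : float, default 1e-6
    update : {"sequential", "batch_mean"}, default "sequential"
        ``sequential`` is the classic Widrow-Hoff recursion (one update
        per pattern, shuffled order); ``batch_mean`` averages the
        gradient over minibatches, which converges far more slowly per
        epoch at the same learning rate.
    center : bool, default True
        Mean-center the features before the recursion (the bias absorbs
        the offset, so the model class is unchanged).  Centering removes
        the dominant DC eigenmode of the feature correlation matrix,
        which otherwise puts dense hidden codes far past the delta
        rule's stability bound at the stated learning rate.
    random_state : int or None
        Seeds the epoch shuffling.

    Attributes
    ----------
    weights_ : ndarray (n_outputs, n_features)
    bias_ : ndarray (n_outputs,)
        Bias in raw (uncentered) feature space.
    """

    def __init__(self, learning_rate: float = 0.07, n_epochs: int = 250,
                 batch_size: int = 20, weight_decay: float = 1e-6,
                 update: str = "sequential", center: bool = True,
                 random_state: int | None = None):
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.update = update
        self.center = center
        self.random_state = random_state

    def fit(self, X, Y) -> "LinearReadout":
        X = np.ascontiguousarray(X, dtype=float)
        Y = np.ascontiguousarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or len(X) != len(Y):
            raise ValueError("X and Y must be aligned 2-d arrays")
        n, n_feat = X.shape
        n_out = Y.shape[1]
        mu = X.mean(axis=0) if self.center else np.zeros(n_feat)
        if self.center:
            X = X - mu
        rng = np.random.default_rng(self.random_state)
        W = np.zeros((n_out, n_feat))
        b = np.zeros(n_out)
        lr = self.learning_rate
        decay = 1.0 - lr * self.weight_decay
        if self.update == "sequential":
            alpha = 1.0
            for _ in range(self.n_epochs):
                alpha = _lms_epoch(X, Y, W, b, rng.permutation(n), lr,
                                   alpha, decay)
                if not np.isfinite(alpha) or not np.isfinite(b).all():
                    raise FloatingPointError("read-out training diverged")
            W *= alpha
        elif self.update == "batch_mean":
            for _ in range(self.n_epochs):
                order = rng.permutation(n)
                for start in range(0, n, self.batch_size):
                    idx = order[start:start + self.batch_size]
                    xb = X[idx]
                    err = Y[idx] - xb @ W.T
                    err -= b
                    W *= decay
                    W += (lr / len(idx)) * (err.T @ xb)
                    b += lr * err.mean(axis=0)
        else:
            raise ValueError(f"unknown update rule {self.update!r}")
        if not np.isfinite(W).all():
            raise FloatingPointError("read-out training diverged")
        self.weights_ = W
        self.bias_ = b - W @ mu  # back to raw feature space
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        return np.asarray(X, dtype=float) @ self.weights_.T + self.bias_

    # ----- serialization ----------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self, "weights_")
        with h5py.File(path, "w") as fh:
            fh.attrs["estimator"] = "LinearReadout"
            for k, val in self.get_params().items():
                fh.attrs[f"param_{k}"] = "none" if val is None else val
            fh.create_dataset("weights", data=self.weights_)
            fh.create_dataset("bias", data=self.bias_)

    @classmethod
    def load(cls, path) -> "LinearReadout":
        with h5py.File(path, "r") as fh:
            params = {k[6:]: (None if isinstance(v, str) and v == "none"
                              else v)
                      for k, v in fh.attrs.items() if k.startswith("param_")}
            for key in ("n_epochs", "batch_size"):
                params[key] = int(params[key])
            if params.get("random_state") is not None:
                params["random_state"] = int(params["random_state"])
            model = cls(**params)
            model.weights_ = fh["weights"][...]
            model.bias_ = fh["bias"][...]
        return model


def train_readout(hidden, targets, **hyper) -> LinearReadout:
    """Train a :class:`LinearReadout`; keywords as in the class."""
    return LinearReadout(**hyper).fit(hidden, targets)


def evaluate_readout(model: LinearReadout, hidden, target_maps,
                     target_positions, cfg: SpaceConfig | None = None,
                     success_threshold: float = 3.0,
                     clip_negative: bool = False) -> ReadoutReport:
    """Evaluate a trained read-out against ground-truth targets.

    ``rmse`` compares predicted and target maps element-wise; the COM error
    is the mean Euclidean distance in degrees between the decoded and true
    target positions (decoded from raw outputs by default, see
    :func:`decode_com`).  ``success`` is strict: mean COM error < 3 deg.
    """
    cfg = cfg or SpaceConfig()
    pred = model.predict(hidden)
    target_maps = np.asarray(target_maps, dtype=float)
    rmse = float(np.sqrt(((pred - target_maps) ** 2).mean()))
    com = decode_com(pred, cfg, clip_negative=clip_negative)
    dist = np.linalg.norm(com - np.asarray(target_positions, dtype=float),
                          axis=1)
    mean = float(dist.mean())
    return ReadoutReport(rmse=rmse, com_error_mean=mean,
                         com_error_sd=float(dist.std()),
                         success=bool(mean < success_threshold),
                         n_patterns=len(dist))
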