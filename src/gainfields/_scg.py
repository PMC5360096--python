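"""Scaled conjugate gradient minimization (Moller, 1993).

Batch second-order method that avoids line searches by scaling a
finite-difference Hessian-vector estimate with a Levenberg-Marquardt style
trust parameter.  Steps are accepted only when they decrease the objective,
so the returned loss trace is non-increasing.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["scg_minimize"]


def scg_minimize(fun: Callable[[np.ndarray], tuple[float, np.ndarray]],
                 x0: np.ndarray, n_iters: int,
                 callback: Callable[[int, float], None] | None = None,
                 sigma0: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Minimize ``fun`` (returning value and gradient) for ``n_iters`` steps.

    Returns the final parameter vector and the trace of accepted objective
    values (one entry per iteration; on rejected steps the previous value is
    repeated).
    """
    x = np.asarray(x0, dtype=float).copy()
    f, g = fun(x)
    r = -g
    p = r.copy()
    lamb = 1e-6
    lamb_bar = 0.0
    success = True
    delta = 0.0
    n_params = len(x)
    trace = np.empty(n_iters)
    for k in range(n_iters):
        p_sq = float(p @ p)
        if p_sq == 0.0:  # gradient vanished: converged
            trace[k:] = f
            break
        if success:
            sigma = sigma0 / np.sqrt(p_sq)
            _, g_plus = fun(x + sigma * p)
            s = (g_plus - g) / sigma
            delta = float(p @ s)
        # scale the curvature estimate
        delta += (lamb - lamb_bar) * p_sq
        if delta <= 0.0:  # make the Hessian estimate positive definite
            lamb_bar = 2.0 * (lamb - delta / p_sq)
            delta = -delta + lamb * p_sq
            lamb = lamb_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, g_new = fun(x + alpha * p)
        comparison = 2.0 * delta * (f - f_new) / (mu ** 2)
        if comparison >= 0.0:  # successful step
            x = x + alpha * p
            f = f_new
            g = g_new
            r_new = -g
            lamb_bar = 0.0
            success = True
            if (k + 1) % n_params == 0:  # periodic restart
                p = r_new.copy()
            else:
                beta = float((r_new @ r_new - r_new @ r) / mu)
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lamb = max(lamb * 0.25, 1e-15)
        else:
            lamb_bar = lamb
            success = False
        if comparison < 0.25:
            lamb += delta * (1.0 - comparison) / p_sq
        if not np.isfinite(f):
            raise FloatingPointError("SCG objective became non-finite")
        trace[k] = f
        if callback is not None:
            callback(k, f)
    return x, trace
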