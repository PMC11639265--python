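"""Logistic-regression prediction core.

Parameter layout is bias-first everywhere in the package: a candidate vector
``theta`` of length ``D = N + 1`` stores the bias at ``theta[0]`` and one
weight per feature in ``theta[1:]``.  Candidate batches stack such vectors
as rows of a ``K x D`` array.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .exceptions import InvalidInputError, ShapeError

__all__ = ["sigmoid", "predict_proba", "predict_class", "cross_entropy_cost", "PROB_EPS"]

#: probabilities are clipped to [PROB_EPS, 1 - PROB_EPS] before logs
PROB_EPS = 1e-12


def sigmoid(a):
    """Elementwise logistic function ``1 / (1 + exp(-a))``.

    Parameters
    ----------
    a : scalar or array-like
        Finite input values.

    Returns
    -------
    Same shape as the input, values in ``(0, 1)`` (up to float underflow at
    extreme arguments).
    """
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise InvalidInputError("sigmoid input must be finite")
    out = expit(a)
    return out if out.ndim else float(out)


def _split_params(params, n_features):
    params = np.asarray(params, dtype=float)
    if params.ndim not in (1, 2):
        raise ShapeError("params must be a vector or a 2-D batch of vectors")
    if params.shape[-1] != n_features + 1:
        raise ShapeError(
            f"params length {params.shape[-1]} != n_features + 1 = {n_features + 1}"
        )
    if not np.all(np.isfinite(params)):
        raise InvalidInputError("params must be finite")
    b = params[..., 0]
    w = params[..., 1:]
    return b, w


def predict_proba(params, X):
    """Class-1 probabilities ``sigmoid(X @ w.T + b)`` for one or many candidates.

    Parameters
    ----------
    params : array, shape (D,) or (K, D)
        Bias-first parameter vector(s), ``D = N + 1``.
    X : array, shape (M, N)
        Feature matrix.

    Returns
    -------
    array of shape ``(M,)`` for a single vector, ``(K, M)`` for a batch.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ShapeError("X must be 2-D (instances x features)")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("X must be finite")
    b, w = _split_params(params, X.shape[1])
    if w.ndim == 1:
        return expit(X @ w + b)
    return expit(X @ w.T + b).T


def predict_class(p):
    """Threshold probabilities at 0.5: label 1 iff ``p >= 0.5``."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise InvalidInputError("probabilities must lie in [0, 1]")
    return (p >= 0.5).astype(np.int64)


def cross_entropy_cost(params, X, y):
    """Summed cross-entropy cost ``-sum(y log p + (1-y) log(1-p))``.

    The cost is a sum over instances, not a mean.  Probabilities are clipped
    to ``[PROB_EPS, 1 - PROB_EPS]`` so the result stays finite.  Accepts a
    single vector (returns a scalar) or a batch (returns one cost per row).
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise InvalidInputError("empty dataset")
    p = predict_proba(params, X)
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    j = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum(axis=-1)
    return j if j.ndim else float(j)
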