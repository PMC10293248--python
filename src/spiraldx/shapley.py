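"""Exact Shapley-value attribution by coalition enumeration.

For a model with p features (p <= 16 here; the pipeline has at most 14) the
interventional Shapley value of feature i for a sample x against a background
set Z is

    φ_i(x) = Σ_{S ⊆ N\\{i}}  |S|!(p−|S|−1)!/p!  · (v(S ∪ {i}) − v(S)),

with the coalition game  v(S) = mean_{z ∈ Z} f(x_S, z_{N\\S})  — features in S
take the sample's values, the rest the background's.  Because p is small the
2^p coalition values are enumerated exactly in float64, so the attributions
satisfy the additivity identity

    Σ_i φ_i(x) + v(∅) = f(x)

to machine precision (v(∅) is the base value, the mean model output on the
background).  ``f`` is evaluated on the model-output (log-odds) scale.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .errors import DomainError

MAX_FEATURES = 16


def _coalition_masks(p: int) -> np.ndarray:
    """Boolean matrix (2^p, p): row s is the membership of coalition s."""
    subsets = np.arange(1 << p, dtype=np.uint32)
    return (subsets[:, None] >> np.arange(p, dtype=np.uint32)[None, :]) & 1 == 1


def _shapley_weights(p: int) -> np.ndarray:
    """w[k] = k!(p−k−1)!/p! for coalition size k (0..p−1)."""
    fact = [math.factorial(i) for i in range(p + 1)]
    return np.array([fact[k] * fact[p - k - 1] / fact[p] for k in range(p)])


def exact_shapley(predict: Callable[[np.ndarray], np.ndarray],
                  X: np.ndarray,
                  background: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact Shapley values for each row of X.

    Parameters
    ----------
    predict : callable mapping an (m, p) array to m raw model outputs.
    X : (n, p) samples to explain.
    background : (B, p) reference rows defining the coalition game.

    Returns
    -------
    phi : (n, p) signed attributions on the model-output scale.
    base_value : mean model output over the background.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    n, p = X.shape
    if p != Z.shape[1]:
        raise DomainError("sample and background dimensionality differ")
    if p > MAX_FEATURES:
        raise DomainError(
            f"exact enumeration supports at most {MAX_FEATURES} features, got {p}"
        )
    masks = _coalition_masks(p)            # (2^p, p)
    sizes = masks.sum(axis=1)              # |S| per coalition
    weights_by_size = _shapley_weights(p)  # (p,)
    n_coal, B = masks.shape[0], Z.shape[0]

    # per feature: coalition indices without i, paired with the same + i
    idx_all = np.arange(n_coal, dtype=np.uint32)
    pairs = []
    for i in range(p):
        without = idx_all[~masks[:, i]]
        pairs.append((without, without | np.uint32(1 << i),
                      weights_by_size[sizes[without]]))

    phi = np.empty((n, p))
    base_value = float(np.mean(predict(Z)))
    for row in range(n):
        x = X[row]
        # hybrid rows for all coalitions x backgrounds, masked in one batch
        hybrids = np.where(masks[:, None, :], x[None, None, :], Z[None, :, :])
        preds = np.asarray(predict(hybrids.reshape(n_coal * B, p)), dtype=float)
        v = preds.reshape(n_coal, B).mean(axis=1)
        for i, (without, with_i, w) in enumerate(pairs):
            phi[row, i] = np.dot(w, v[with_i] - v[without])
    return phi, base_value
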