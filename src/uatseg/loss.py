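"""Uncertainty-weighted binary cross-entropy.

The weight map is ``W = 1 + gamma * U`` for an uncertainty map ``U >= 0`` and
strength ``gamma >= 0``, so no pixel is ever down-weighted and ``gamma = 0``
recovers plain BCE. The loss is

    L_wBCE = -(1/N) sum_i W_i [ Y_i ln p_i + (1 - Y_i) ln(1 - p_i) ]

normalised by the pixel count N (not by the weight sum). Both the weighted
loss (used for backpropagation) and the unweighted loss (used for early
stopping and validation) are computed in one pass. Weights are plain numbers
derived from detached predictions: they never carry a derivative path, so a
model cannot lower its loss by suppressing its own uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .uncertainty import _as_binary_mask, _as_prob_array

__all__ = ["EPS", "LossValue", "weight_map", "weighted_bce", "bce_terms"]

#: Probability clamp used inside the loss so saturated pixels stay finite.
EPS = 1e-7


@dataclass(frozen=True)
class LossValue:
    """Weighted and unweighted mean BCE over the same N pixels (nats/pixel)."""

    weighted: float
    unweighted: float
    n_pixels: int


def weight_map(u, gamma: float) -> np.ndarray:
    """Per-pixel loss weights ``1 + gamma * U``."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    arr = np.asarray(u, dtype=np.float64)
    if not np.all(np.isfinite(arr)) or arr.size and arr.min() < 0:
        raise ValueError("uncertainty map must be finite and nonnegative")
    return 1.0 + gamma * arr


def bce_terms(probs, truth) -> np.ndarray:
    """Per-pixel BCE terms ``-(Y ln p + (1-Y) ln(1-p))`` with p clamped to
    [EPS, 1-EPS]."""
    p = np.clip(_as_prob_array(probs), EPS, 1.0 - EPS)
    t = _as_binary_mask(truth, like=p)
    return -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))


def weighted_bce(probs, truth, weights=None, gamma: float | None = None,
                 uncertainty=None) -> LossValue:
    """Mean weighted and unweighted BCE over a probability map.

    Weights may be passed directly (``weights``) or built on the fly from an
    uncertainty map and ``gamma``. With all weights 1 the two losses are
    identical.
    """
    terms = bce_terms(probs, truth)
    if weights is None:
        if uncertainty is not None:
            weights = weight_map(uncertainty, 0.0 if gamma is None else gamma)
        else:
            weights = np.ones_like(terms)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != terms.shape:
        raise ValueError(f"weight shape {w.shape} does not match map shape {terms.shape}")
    n = terms.size
    return LossValue(
        weighted=float(np.sum(w * terms) / n),
        unweighted=float(np.mean(terms)),
        n_pixels=int(n),
    )
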