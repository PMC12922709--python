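"""Per-pixel uncertainty maps for binary segmentation.

Three uncertainty quantification (UQ) routes are provided, all producing a
nonnegative per-pixel map ``U`` over the same grid as the input probabilities:

* :func:`entropy_map` — binary Shannon entropy of the predicted foreground
  probability (natural-log units, maximum ``ln 2`` at p = 0.5);
* split conformal prediction with the Least Ambiguous Set-Valued Classifier
  (LAC) score — :func:`lac_scores`, :func:`conformal_quantile`,
  :func:`conformal_map`, wrapped by the :class:`ConformalCalibrator`
  estimator; the resulting map is binary (1 where the two-class prediction
  set is not a singleton);
* :func:`variance_map` — per-pixel population variance across the M output
  heads of a multi-output model (bounded by 0.25 for probabilities).

Maps can be exported as 32-bit float TIFF for analysis or rescaled 8-bit PNG
heatmaps for visualisation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import tifffile
from PIL import Image
from scipy.special import xlogy
from sklearn.base import BaseEstimator

__all__ = [
    "LN2",
    "ConformalCalibration",
    "ConformalCalibrator",
    "entropy_map",
    "lac_scores",
    "conformal_quantile",
    "prediction_sets",
    "conformal_map",
    "variance_map",
    "save_uncertainty_tiff",
    "save_uncertainty_png",
]

#: Maximum binary entropy (nats), attained at p = 0.5.
LN2 = math.log(2.0)

#: Default cap on the pooled calibration-score count; larger pools are
#: subsampled uniformly at random (seeded) to bound memory.
MAX_CALIBRATION_POOL = 1_000_000


def _as_prob_array(probs) -> np.ndarray:
    p = np.asarray(probs, dtype=np.float64)
    if p.size == 0:
        raise ValueError("probability map is empty")
    if not np.all(np.isfinite(p)):
        raise ValueError("probability map contains non-finite values")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    return p


def _as_binary_mask(truth, like: np.ndarray | None = None) -> np.ndarray:
    t = np.asarray(truth)
    if like is not None and t.shape != like.shape:
        raise ValueError(
            f"mask shape {t.shape} does not match probability map shape {like.shape}"
        )
    vals = np.unique(t)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("ground-truth mask must be binary (values in {0, 1})")
    return t.astype(np.float64)


def entropy_map(probs) -> np.ndarray:
    """Binary entropy per pixel, ``U = -p ln p - (1-p) ln(1-p)``.

    Uses the 0·log 0 := 0 convention, so the map is exactly 0 where the
    probability is 0 or 1 and attains its maximum ``ln 2`` at p = 0.5.
    """
    p = _as_prob_array(probs)
    return -xlogy(p, p) - xlogy(1.0 - p, 1.0 - p)


def lac_scores(probs, truth) -> np.ndarray:
    """LAC conformity scores ``s = 1 - p_y``: one minus the probability the
    model assigned to the true class of each pixel.

    For a foreground pixel the score is ``1 - p``; for a background pixel it
    is ``1 - (1 - p) = p``. Scores lie in [0, 1]; small scores mean the model
    was confident and correct.
    """
    p = _as_prob_array(probs)
    t = _as_binary_mask(truth, like=p)
    return np.where(t == 1.0, 1.0 - p, p)


@dataclass(frozen=True)
class ConformalCalibration:
    """Fitted split-conformal state.

    Parameters
    ----------
    alpha : target error rate in (0, 1); 1 - alpha is the coverage level.
    n_cal : number of pooled calibration pixels used for the quantile.
    q_hat : the ⌈(1-alpha)(n_cal+1)⌉-th smallest calibration score, clamped
        to 1 when that rank exceeds n_cal (conservative full sets).
    seed : seed used if the calibration pool was subsampled.
    """

    alpha: float
    n_cal: int
    q_hat: float
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly inside (0, 1)")
        if self.n_cal < 1:
            raise ValueError("n_cal must be >= 1")
        if not 0.0 <= self.q_hat <= 1.0:
            raise ValueError("q_hat must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ConformalCalibration":
        return cls(**json.loads(text))


def conformal_quantile(scores, alpha: float, seed: int = 0,
                       max_pool: int = MAX_CALIBRATION_POOL) -> ConformalCalibration:
    """Finite-sample conformal quantile of a pool of LAC scores.

    ``q_hat`` is the k-th smallest score with ``k = ceil((1-alpha)(n+1))``
    (no interpolation: the guarantee is stated for order statistics). When
    ``k > n`` — too few calibration points for the requested coverage — the
    quantile is clamped to 1, which forces full prediction sets.

    ``scores`` may be a single array or a sequence of arrays (e.g. one per
    calibration image); all pixels are pooled. Pools larger than ``max_pool``
    are subsampled uniformly at random with ``seed``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly inside (0, 1)")
    if isinstance(scores, np.ndarray):
        pool = scores.ravel().astype(np.float64)
    elif np.isscalar(scores):
        pool = np.array([scores], dtype=np.float64)
    else:
        parts = [np.asarray(s, dtype=np.float64).ravel() for s in scores]
        pool = np.concatenate(parts) if parts else np.empty(0)
    if pool.size == 0:
        raise ValueError("cannot calibrate on an empty score collection")
    if not np.all(np.isfinite(pool)):
        raise ValueError("calibration scores contain non-finite values")
    if pool.size > max_pool:
        rng = np.random.default_rng(seed)
        pool = rng.choice(pool, size=max_pool, replace=False)
    n = int(pool.size)
    k = math.ceil((1.0 - alpha) * (n + 1))
    if k > n:
        q_hat = 1.0
    else:
        q_hat = float(np.partition(pool, k - 1)[k - 1])
    return ConformalCalibration(alpha=alpha, n_cal=n, q_hat=q_hat, seed=seed)


def prediction_sets(probs, calib: ConformalCalibration):
    """Two-class LAC prediction-set membership per pixel.

    A class y belongs to the set when its probability is at least
    ``1 - q_hat``. Returns ``(in_background, in_foreground)`` boolean arrays.
    """
    if not isinstance(calib, ConformalCalibration):
        raise ValueError("calib must be a fitted ConformalCalibration")
    p1 = _as_prob_array(probs)
    thr = 1.0 - calib.q_hat
    return (1.0 - p1) >= thr, p1 >= thr


def conformal_map(probs, calib: ConformalCalibration) -> np.ndarray:
    """Binary conformal uncertainty map.

    A pixel is uncertain (U = 1) when its two-class prediction set is not a
    singleton — both classes pass the threshold, or neither does. Pixels
    whose set is a single class get U = 0.
    """
    in0, in1 = prediction_sets(probs, calib)
    set_size = in0.astype(np.int64) + in1.astype(np.int64)
    return (set_size != 1).astype(np.float64)


def variance_map(outputs) -> np.ndarray:
    """Per-pixel population variance across M >= 2 model outputs.

    ``U = (1/M) Σ_m (Ŷ_m − Ȳ)²`` with ``Ȳ`` the per-pixel mean of the M
    probability maps. Zero exactly where all outputs agree; at most 0.25 for
    probabilities in [0, 1] (the two-point {0, 1} configuration).
    """
    stack = np.stack([_as_prob_array(o) for o in outputs], axis=0)
    if stack.shape[0] < 2:
        raise ValueError("variance requires at least M = 2 outputs")
    shapes = {o.shape for o in stack[:, None][:, 0]}
    if len(shapes) != 1:  # np.stack already enforces this; keep a clear message
        raise ValueError("all outputs must share the same grid")
    # shifted-data form: exactly 0 when all outputs agree, and numerically
    # stable for values in [0, 1]
    d = stack - stack[0]
    m = d.mean(axis=0)
    return np.maximum(np.mean(d * d, axis=0) - m * m, 0.0)


class ConformalCalibrator(BaseEstimator):
    """Split-conformal calibrator for per-pixel binary classification (LAC).

    Pools LAC scores from the calibration images, stores the finite-sample
    quantile ``q_hat_`` and turns new probability maps into binary
    uncertainty maps via :meth:`transform`.

    Parameters
    ----------
    alpha : float, default 0.1
        Target pixelwise error rate; the marginal coverage guarantee is that
        the true class falls inside the prediction set with probability at
        least ``1 - alpha`` under exchangeability.
    max_pool : int
        Calibration pixels beyond this count are subsampled (seeded).
    random_state : int, default 0
        Seed for the subsampling step.
    """

    def __init__(self, alpha: float = 0.1, max_pool: int = MAX_CALIBRATION_POOL,
                 random_state: int = 0):
        self.alpha = alpha
        self.max_pool = max_pool
        self.random_state = random_state

    def fit(self, probs, truth):
        """Fit on calibration data.

        ``probs`` / ``truth`` are either single arrays or equal-length
        sequences of per-image arrays.
        """
        if isinstance(probs, np.ndarray):
            probs, truth = [probs], [truth]
        scores = [lac_scores(p, t) for p, t in zip(probs, truth, strict=True)]
        self.calibration_ = conformal_quantile(
            scores, self.alpha, seed=self.random_state, max_pool=self.max_pool
        )
        self.q_hat_ = self.calibration_.q_hat
        self.n_cal_ = self.calibration_.n_cal
        return self

    def transform(self, probs) -> np.ndarray:
        """Binary uncertainty map for a new probability map."""
        self._check_fitted()
        return conformal_map(probs, self.calibration_)

    def prediction_sets(self, probs):
        self._check_fitted()
        return prediction_sets(probs, self.calibration_)

    def _check_fitted(self):
        if not hasattr(self, "calibration_"):
            raise RuntimeError("ConformalCalibrator is not fitted; call fit() first")


def save_uncertainty_tiff(u, path) -> None:
    """Write an uncertainty map as a single-page 32-bit float TIFF."""
    arr = np.asarray(u, dtype=np.float32)
    tifffile.imwrite(str(path), arr)


def save_uncertainty_png(u, path, vmax: float | None = None) -> None:
    """Write an 8-bit PNG heatmap, rescaling [0, vmax] to [0, 255].

    ``vmax`` defaults to the map maximum (or 1 for an all-zero map).
    """
    arr = np.asarray(u, dtype=np.float64)
    if vmax is None:
        vmax = float(arr.max()) or 1.0
    scaled = np.clip(arr / vmax, 0.0, 1.0)
    img = np.round(scaled * 255.0).astype(np.uint8)
    Image.fromarray(img, mode="L").save(str(path))
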