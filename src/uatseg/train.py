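"""Uncertainty-aware training (UAT) of the segmentation fixture.

The central estimator is :class:`UATSegmenter`, a scikit-learn-style model
with ``fit`` / ``predict`` / ``predict_proba`` / ``score``. Training follows
the UAT schedule:

1. *Warmup*: for the first ``n_warmup`` epochs every method (including
   baseline) optimises plain, unweighted BCE — the model is allowed to learn
   normally before being asked to consider its own uncertainty.
2. After warmup, every batch gets a per-pixel uncertainty map ``U`` computed
   from the current model's detached predictions — entropy of the primary
   map, variance across the output heads, or the binary conformal map under
   the current quantile — and the loss becomes weighted BCE with
   ``W = 1 + gamma * U``.
3. Conformal only: the quantile ``q_hat`` is first fitted on the calibration
   split at the end of epoch ``n_warmup`` (applied from epoch
   ``n_warmup + 1``) and refitted after every further ``n_warmup`` epochs.
4. Early stopping watches the *unweighted* validation loss with the given
   patience; the best-validation checkpoint is restored at the end.

Weights are computed in plain numpy from forward passes, so by construction
they carry no derivative path back into the model — the gradient-isolation
contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import uncertainty as uq
from .loss import EPS, weight_map
from .model import SegModelSpec, MultiHeadUNet, build_model
from .nn import Adam, sigmoid
from .stats import dice

__all__ = [
    "TrainingConfig",
    "RunRecord",
    "UATSegmenter",
    "run_training",
    "early_stop_decision",
    "epoch_uncertainty_summary",
]

METHODS = ("baseline", "entropy", "variance", "conformal")


@dataclass(frozen=True)
class TrainingConfig:
    """One training run's hyperparameters.

    Defaults follow the reference protocol: Adam with learning rate and
    weight decay 1e-5, batch size 1, early-stopping patience 5, at most 40
    epochs. ``gamma`` is the uncertainty weighting strength, ``n_warmup``
    the warmup length (and conformal recalibration interval), ``alpha`` the
    conformal error rate (required iff method == "conformal").
    """

    method: str = "baseline"
    gamma: float = 1.0
    n_warmup: int = 1
    alpha: float | None = None
    learning_rate: float = 1e-5
    weight_decay: float = 1e-5
    patience: int = 5
    max_epochs: int = 40
    batch_size: int = 1
    run_seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_warmup < 1 or self.patience < 1 or self.max_epochs < 1:
            raise ValueError("n_warmup, patience and max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.method == "conformal":
            if self.alpha is None:
                raise ValueError("method='conformal' requires alpha")
            if not 0.0 < self.alpha < 1.0:
                raise ValueError("alpha must lie in (0, 1)")


@dataclass
class RunRecord:
    """Per-epoch trace and summary of one training run."""

    epochs: pd.DataFrame
    convergence_epoch: int
    stopped_epoch: int
    test_dice: float | None
    q_hat_history: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.epochs.to_csv(path, index=False)


def early_stop_decision(val_losses, patience: int):
    """Simulate early stopping on a sequence of per-epoch validation losses.

    The best epoch is the (first) minimum; training halts after the first
    epoch ``e`` with ``e - best_epoch >= patience`` (a tie is not an
    improvement), or at the end of the sequence. Returns
    ``(stop_epoch, best_epoch)``, both 1-based.
    """
    losses = list(val_losses)
    if not losses:
        raise ValueError("need at least one validation loss")
    if patience < 1:
        raise ValueError("patience must be >= 1")
    best_epoch, best = 1, losses[0]
    for e, v in enumerate(losses[1:], start=2):
        if v < best:
            best, best_epoch = v, e
        if e - best_epoch >= patience:
            return e, best_epoch
    return len(losses), best_epoch


def epoch_uncertainty_summary(maps) -> float:
    """Pixel-weighted mean uncertainty over an epoch's batch maps."""
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one uncertainty map")
    total = sum(float(np.sum(m)) for m in maps)
    pixels = sum(int(np.asarray(m).size) for m in maps)
    return total / pixels


def _stack_images(X) -> np.ndarray:
    """Normalise input images to a float64 (N, C, H, W) batch."""
    arr = np.asarray(X, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[:, None]
    if arr.ndim != 4:
        raise ValueError("expected images of shape (N, H, W) or (N, C, H, W)")
    return arr


class UATSegmenter(BaseEstimator):
    """Binary segmenter trained with uncertainty-weighted cross-entropy.

    Parameters mirror :class:`TrainingConfig` plus the fixture-model
    architecture. ``random_state`` seeds the per-epoch shuffling (the run
    seed); ``model_seed`` seeds weight initialisation.

    Fitted attributes
    -----------------
    model_ : the trained :class:`MultiHeadUNet` (best-validation weights).
    record_ : :class:`RunRecord` with the per-epoch trace.
    best_epoch_, stopped_epoch_ : early-stopping outcome (1-based).
    calibrator_ : final conformal state (conformal method only).
    """

    def __init__(self, method: str = "baseline", gamma: float = 1.0,
                 n_warmup: int = 1, alpha: float | None = None,
                 learning_rate: float = 1e-5, weight_decay: float = 1e-5,
                 patience: int = 5, max_epochs: int = 40, batch_size: int = 1,
                 in_channels: int = 1, base_width: int = 8, depth: int = 2,
                 m_heads: int = 3, head_init: str = "random",
                 model_seed: int = 0, random_state: int = 0):
        self.method = method
        self.gamma = gamma
        self.n_warmup = n_warmup
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.patience = patience
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.in_channels = in_channels
        self.base_width = base_width
        self.depth = depth
        self.m_heads = m_heads
        self.head_init = head_init
        self.model_seed = model_seed
        self.random_state = random_state

    # -- configuration plumbing ------------------------------------------------

    def _training_config(self) -> TrainingConfig:
        return TrainingConfig(
            method=self.method, gamma=self.gamma, n_warmup=self.n_warmup,
            alpha=self.alpha, learning_rate=self.learning_rate,
            weight_decay=self.weight_decay, patience=self.patience,
            max_epochs=self.max_epochs, batch_size=self.batch_size,
            run_seed=self.random_state,
        )

    def _model_spec(self) -> SegModelSpec:
        return SegModelSpec(in_channels=self.in_channels,
                            base_width=self.base_width, depth=self.depth,
                            m_heads=self.m_heads, seed=self.model_seed,
                            head_init=self.head_init)

    # -- training --------------------------------------------------------------

    def _batch_uncertainty(self, head_probs: np.ndarray, primary: np.ndarray,
                           calibration) -> np.ndarray:
        if self.method == "entropy":
            return uq.entropy_map(primary)
        if self.method == "variance":
            mean = head_probs.mean(axis=1, keepdims=True)
            return np.mean((head_probs - mean) ** 2, axis=1)
        if self.method == "conformal":
            if calibration is None:
                raise RuntimeError("conformal weighting requested before calibration")
            return uq.conformal_map(primary, calibration)
        raise AssertionError(self.method)

    def _forward_primary(self, model, xb):
        logits, cache = model.forward(xb)
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite model activations")
        head_probs = sigmoid(logits)
        return head_probs, head_probs.mean(axis=1), cache

    def _fit_conformal(self, model, X_cal, y_cal, epoch):
        scores = []
        for i in range(X_cal.shape[0]):
            _, primary, _ = self._forward_primary(model, X_cal[i:i + 1])
            scores.append(uq.lac_scores(primary[0], y_cal[i]))
        calib = uq.conformal_quantile(scores, self.alpha, seed=self.random_state)
        return calib

    def fit(self, X, y, X_val=None, y_val=None, X_cal=None, y_cal=None,
            out_dir=None):
        """Train on (X, y) with early stopping on the validation split.

        X : (N, H, W) or (N, C, H, W) images in [0, 1].
        y : (N, H, W) binary masks.
        X_val, y_val : validation split (required).
        X_cal, y_cal : calibration split (required for method='conformal').
        out_dir : optional run directory for record.csv, manifest, best
            checkpoint and per-epoch first-batch snapshots.
        """
        config = self._training_config()
        spec = self._model_spec()
        X = _stack_images(X)
        y = np.asarray(y, dtype=np.float64)
        if X_val is None or y_val is None:
            raise ValueError("a validation split is required for early stopping")
        X_val = _stack_images(X_val)
        y_val = np.asarray(y_val, dtype=np.float64)
        if config.method == "conformal":
            if X_cal is None or y_cal is None or len(X_cal) == 0:
                raise ValueError("method='conformal' requires a nonempty calibration split")
            X_cal = _stack_images(X_cal)
            y_cal = np.asarray(y_cal, dtype=np.float64)

        model = build_model(spec, method=config.method)
        opt = Adam(model.params, lr=config.learning_rate,
                   weight_decay=config.weight_decay)
        shuffle_rng = np.random.default_rng(config.run_seed)
        out_dir = Path(out_dir) if out_dir is not None else None
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)

        n_train = X.shape[0]
        rows = []
        q_hat_history: list[tuple[int, float]] = []
        calibration = None
        val_losses: list[float] = []
        best_state = model.state_dict()
        best_epoch, best_loss = 0, np.inf
        stopped_epoch = config.max_epochs

        for epoch in range(1, config.max_epochs + 1):
            order = shuffle_rng.permutation(n_train)
            weighting = config.method != "baseline" and epoch > config.n_warmup
            sum_w = sum_u = sum_t = 0.0
            n_pix = 0
            first_batch_snapshot = None
            for start in range(0, n_train, config.batch_size):
                idx = order[start:start + config.batch_size]
                xb, tb = X[idx], y[idx]
                head_probs, primary, cache = self._forward_primary(model, xb)
                if weighting:
                    u_map = self._batch_uncertainty(head_probs, primary, calibration)
                else:
                    u_map = np.zeros_like(primary)
                w_map = weight_map(u_map, config.gamma if weighting else 0.0)
                pc = np.clip(primary, EPS, 1.0 - EPS)
                terms = -(tb * np.log(pc) + (1.0 - tb) * np.log(1.0 - pc))
                sum_w += float(np.sum(w_map * terms))
                sum_t += float(np.sum(terms))
                sum_u += float(np.sum(u_map))
                n_pix += terms.size
                if not np.isfinite(sum_w):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                    )
                # gradient of mean(W * term) wrt primary probability; the
                # clamp bounds the derivative instead of zeroing it, so
                # confidently-wrong saturated pixels keep a corrective signal
                dterm = -tb / pc + (1.0 - tb) / (1.0 - pc)
                dprimary = w_map * dterm / terms.size
                dlogits = dprimary[:, None] * head_probs * (1.0 - head_probs) / spec.m_heads
                grads = model.backward(dlogits, cache)
                opt.step(grads)
                if first_batch_snapshot is None:
                    first_batch_snapshot = (primary[0].copy(), u_map[0].copy())

            val_loss, val_dice, val_snapshot = self._evaluate(
                model, X_val, y_val, calibration, weighting, config)
            val_losses.append(val_loss)

            mean_u = sum_u / n_pix
            rows.append({
                "epoch": epoch,
                "train_loss_weighted": sum_w / n_pix,
                "train_loss_unweighted": sum_t / n_pix,
                "val_loss": val_loss,
                "mean_uncertainty": mean_u,
                "val_dice": val_dice,
            })

            if config.method == "conformal" and epoch % config.n_warmup == 0:
                calibration = self._fit_conformal(model, X_cal, y_cal, epoch)
                q_hat_history.append((epoch, calibration.q_hat))

            if out_dir is not None:
                self._write_snapshots(out_dir, epoch, first_batch_snapshot,
                                      val_snapshot)

            if val_loss < best_loss:
                best_loss, best_epoch = val_loss, epoch
                best_state = model.state_dict()
            if epoch - best_epoch >= config.patience:
                stopped_epoch = epoch
                break
        else:
            stopped_epoch = config.max_epochs

        model.load_state_dict(best_state)
        self.model_ = model
        self.best_epoch_ = best_epoch if best_epoch else 1
        self.stopped_epoch_ = min(stopped_epoch, len(val_losses))
        if config.method == "conformal":
            self.calibrator_ = calibration
        self.record_ = RunRecord(
            epochs=pd.DataFrame(rows),
            convergence_epoch=self.best_epoch_,
            stopped_epoch=self.stopped_epoch_,
            test_dice=None,
            q_hat_history=q_hat_history,
            config=asdict(config) | {"model_spec": asdict(spec)},
        )
        if out_dir is not None:
            self.record_.to_csv(out_dir / "record.csv")
            model.save(out_dir / f"run_{config.run_seed}_best.npz")
            manifest = dict(self.record_.config)
            manifest.update(convergence_epoch=self.best_epoch_,
                            stopped_epoch=self.stopped_epoch_,
                            q_hat_history=q_hat_history,
                            checkpoint=f"run_{config.run_seed}_best.npz")
            (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return self

    def _evaluate(self, model, X_val, y_val, calibration, weighting, config):
        losses, dices = [], []
        snapshot = None
        for i in range(X_val.shape[0]):
            head_probs, primary, _ = self._forward_primary(model, X_val[i:i + 1])
            pc = np.clip(primary[0], EPS, 1.0 - EPS)
            t = y_val[i]
            losses.append(float(np.mean(-(t * np.log(pc) + (1 - t) * np.log(1 - pc)))))
            dices.append(dice(primary[0] >= 0.5, t.astype(bool)))
            if snapshot is None:
                if weighting:
                    u = self._batch_uncertainty(head_probs, primary, calibration)[0]
                else:
                    u = np.zeros_like(primary[0])
                snapshot = (primary[0].copy(), u.copy())
        return float(np.mean(losses)), float(np.mean(dices)), snapshot

    @staticmethod
    def _write_snapshots(out_dir: Path, epoch: int, train_snap, val_snap):
        from PIL import Image

        snaps = out_dir / "snapshots"
        snaps.mkdir(exist_ok=True)
        for tag, snap in (("train", train_snap), ("val", val_snap)):
            if snap is None:
                continue
            pred, unc = snap
            img = np.round(np.clip(pred, 0, 1) * 255).astype(np.uint8)
            Image.fromarray(img, mode="L").save(
                snaps / f"epoch_{epoch}_{tag}_pred.png")
            uq.save_uncertainty_tiff(unc, snaps / f"epoch_{epoch}_{tag}_unc.tif")
            uq.save_uncertainty_png(unc, snaps / f"epoch_{epoch}_{tag}_unc.png")

    # -- inference -------------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("UATSegmenter is not fitted; call fit() first")

    def predict_proba(self, X) -> np.ndarray:
        """Primary (mean-of-heads) probability maps, shape (N, H, W)."""
        self._check_fitted()
        X = _stack_images(X)
        out = []
        for i in range(X.shape[0]):
            _, primary, _ = self._forward_primary(self.model_, X[i:i + 1])
            out.append(primary[0])
        return np.stack(out)

    def predict(self, X) -> np.ndarray:
        """Binary masks at the 0.5 threshold."""
        return (self.predict_proba(X) >= 0.5).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean Dice over the given images/masks."""
        preds = self.predict(X)
        y = np.asarray(y)
        return float(np.mean([dice(p, t) for p, t in zip(preds, y)]))


def run_training(config: TrainingConfig, data, model_spec: SegModelSpec,
                 out_dir=None) -> RunRecord:
    """Run one UAT training from a config and four split collections.

    ``data`` is a dict or 4-tuple of sample lists (train, test, calibration,
    validation) of :class:`~uatseg.synth.SynthSample`. Returns the
    :class:`RunRecord`, including test Dice at the restored best weights.
    """
    if isinstance(data, dict):
        splits = tuple(data[k] for k in ("train", "test", "calibration", "validation"))
    else:
        splits = tuple(data)
    train, test, cal, val = splits
    if not train or not val or not test:
        raise ValueError("train, test and validation splits must be nonempty")
    est = UATSegmenter(
        method=config.method, gamma=config.gamma, n_warmup=config.n_warmup,
        alpha=config.alpha, learning_rate=config.learning_rate,
        weight_decay=config.weight_decay, patience=config.patience,
        max_epochs=config.max_epochs, batch_size=config.batch_size,
        in_channels=model_spec.in_channels, base_width=model_spec.base_width,
        depth=model_spec.depth, m_heads=model_spec.m_heads,
        head_init=model_spec.head_init, model_seed=model_spec.seed,
        random_state=config.run_seed,
    )

    def arrs(part):
        return (np.stack([s.image for s in part]),
                np.stack([s.mask for s in part]))

    Xt, yt = arrs(train)
    Xv, yv = arrs(val)
    Xc, yc = arrs(cal) if cal else (None, None)
    est.fit(Xt, yt, X_val=Xv, y_val=yv, X_cal=Xc, y_cal=yc, out_dir=out_dir)
    Xs, ys = arrs(test)
    record = est.record_
    record.test_dice = est.score(Xs, ys)
    if out_dir is not None:
        manifest_path = Path(out_dir) / "manifest.json"
        manifest = json.loads(manifest_path.read_text())
        manifest["test_dice"] = record.test_dice
        manifest_path.write_text(json.dumps(manifest, indent=2))
    record._estimator = est  # kept for downstream analysis of the fitted model
    return record
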