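"""Tests for the UAT training schedule, early stopping and reproducibility."""

import numpy as np
import pytest

from uatseg import (
    SegModelSpec,
    SplitSpec,
    TrainingConfig,
    early_stop_decision,
    epoch_uncertainty_summary,
    generate_dataset,
    preset,
    run_training,
    split_dataset,
)


def simulate_early_stop(losses, patience):
    """Independent hand-simulation of the early-stopping counter."""
    best, best_epoch = losses[0], 1
    since = 0
    for e, v in enumerate(losses, start=1):
        if e == 1:
            continue
        if v < best:
            best, best_epoch, since = v, e, 0
        else:
            since = e - best_epoch
        if since >= patience:
            return e, best_epoch
    return len(losses), best_epoch


@pytest.fixture(scope="module")
def tiny_splits():
    """A small 32x32 cup-like dataset split four ways."""
    p = preset("cup_like", image_size=32)
    samples = generate_dataset(p, 20, seed=100)
    return split_dataset(samples, SplitSpec((0.5, 0.2, 0.15, 0.15), seed=101))


def tiny_config(**kw):
    base = dict(method="baseline", gamma=2.0, n_warmup=2, learning_rate=1e-3,
                weight_decay=1e-5, patience=5, max_epochs=4, batch_size=1,
                run_seed=7)
    base.update(kw)
    return TrainingConfig(**base)


TINY_SPEC = SegModelSpec(in_channels=1, base_width=4, depth=2, m_heads=3, seed=9)


class TestEarlyStopDecision:
    @pytest.mark.parametrize("losses,patience,expected", [
        ([1.0, 0.9, 0.95, 0.96, 0.97, 0.98, 0.99], 5, (7, 2)),
        ([1.0, 1.0], 1, (2, 1)),
        ([1.0, 0.9, 0.8, 0.7], 5, (4, 4)),          # monotone: never stops early
        ([0.5], 3, (1, 1)),
        ([1.0, 0.9, 0.9, 0.9], 2, (4, 2)),          # ties are not improvements
        ([3, 2, 1, 2, 3, 0.5, 4, 4, 4], 3, (9, 6)),
    ])
    def test_crafted_sequences(self, losses, patience, expected):
        assert early_stop_decision(losses, patience) == expected

    def test_matches_hand_simulation_on_random_sequences(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(1, 30))
            # round to one decimal to provoke ties
            losses = np.round(rng.random(n), 1).tolist()
            patience = int(rng.integers(1, 7))
            assert early_stop_decision(losses, patience) == \
                simulate_early_stop(losses, patience)

    def test_errors(self):
        with pytest.raises(ValueError):
            early_stop_decision([], 3)
        with pytest.raises(ValueError):
            early_stop_decision([1.0], 0)


class TestUncertaintySummary:
    def test_zero_maps(self):
        assert epoch_uncertainty_summary([np.zeros((4, 4))]) == 0.0

    def test_weighted_mean(self):
        maps = [np.full((4, 4), 0.2), np.full((4, 4), 0.4)]
        assert epoch_uncertainty_summary(maps) == pytest.approx(0.3)

    def test_binary_maps_give_ambiguous_fraction(self):
        m = np.zeros((4, 4))
        m[:2] = 1.0
        assert epoch_uncertainty_summary([m]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            epoch_uncertainty_summary([])


class TestTrainingConfig:
    def test_defaults_follow_protocol(self):
        cfg = TrainingConfig()
        assert (cfg.learning_rate, cfg.weight_decay) == (1e-5, 1e-5)
        assert (cfg.patience, cfg.max_epochs, cfg.batch_size) == (5, 40, 1)

    def test_conformal_requires_alpha(self):
        with pytest.raises(ValueError, match="alpha"):
            TrainingConfig(method="conformal")

    @pytest.mark.parametrize("kw", [
        {"gamma": -1}, {"n_warmup": 0}, {"patience": 0}, {"method": "bogus"},
        {"method": "conformal", "alpha": 1.5},
    ])
    def test_invalid_configs(self, kw):
        with pytest.raises(ValueError):
            TrainingConfig(**kw)


class TestSchedule:
    def test_baseline_has_zero_uncertainty_everywhere(self, tiny_splits):
        rec = run_training(tiny_config(method="baseline", gamma=3.0), tiny_splits,
                           TINY_SPEC)
        assert np.all(rec.epochs["mean_uncertainty"].to_numpy() == 0.0)
        np.testing.assert_allclose(rec.epochs["train_loss_weighted"],
                                   rec.epochs["train_loss_unweighted"], atol=1e-12)

    def test_warmup_is_bit_identical_to_baseline(self, tiny_splits):
        cols = ["train_loss_weighted", "train_loss_unweighted", "val_loss",
                "val_dice"]
        recs = {}
        for method in ("baseline", "entropy", "variance"):
            cfg = tiny_config(method=method, n_warmup=2, max_epochs=3)
            recs[method] = run_training(cfg, tiny_splits, TINY_SPEC).epochs
        for method in ("entropy", "variance"):
            np.testing.assert_array_equal(
                recs[method].iloc[:2][cols].to_numpy(),
                recs["baseline"].iloc[:2][cols].to_numpy(),
            )

    def test_entropy_weighting_starts_after_warmup(self, tiny_splits):
        cfg = tiny_config(method="entropy", n_warmup=3, max_epochs=6,
                          patience=6, gamma=2.0)
        rec = run_training(cfg, tiny_splits, TINY_SPEC).epochs
        w = rec["train_loss_weighted"].to_numpy()
        u = rec["train_loss_unweighted"].to_numpy()
        mu = rec["mean_uncertainty"].to_numpy()
        np.testing.assert_array_equal(w[:3], u[:3])
        assert np.all(mu[:3] == 0.0)
        assert np.all(mu[3:] > 0.0)
        assert np.all(w[3:] >= u[3:])

    def test_conformal_refit_schedule(self, tiny_splits):
        cfg = tiny_config(method="conformal", alpha=0.2, n_warmup=2,
                          max_epochs=7, patience=7)
        rec = run_training(cfg, tiny_splits, TINY_SPEC)
        assert [e for e, _ in rec.q_hat_history] == [2, 4, 6]
        np.testing.assert_array_equal(
            rec.epochs["train_loss_weighted"].to_numpy()[:2],
            rec.epochs["train_loss_unweighted"].to_numpy()[:2],
        )
        for _, q in rec.q_hat_history:
            assert 0.0 <= q <= 1.0

    def test_conformal_needs_calibration_split(self, tiny_splits):
        train, test, _, val = tiny_splits
        cfg = tiny_config(method="conformal", alpha=0.2)
        with pytest.raises(ValueError, match="calibration"):
            run_training(cfg, (train, test, [], val), TINY_SPEC)

    def test_gamma_zero_matches_unweighted_end_to_end(self, tiny_splits):
        cfg = tiny_config(method="entropy", gamma=0.0, n_warmup=1, max_epochs=3)
        rec = run_training(cfg, tiny_splits, TINY_SPEC).epochs
        np.testing.assert_allclose(rec["train_loss_weighted"],
                                   rec["train_loss_unweighted"], atol=1e-10)

    def test_reproducibility_bit_exact(self, tiny_splits):
        cfg = tiny_config(method="entropy", max_epochs=3)
        a = run_training(cfg, tiny_splits, TINY_SPEC)
        b = run_training(cfg, tiny_splits, TINY_SPEC)
        np.testing.assert_array_equal(a.epochs.to_numpy(), b.epochs.to_numpy())
        assert a.test_dice == b.test_dice

    def test_record_invariants(self, tiny_splits):
        rec = run_training(tiny_config(max_epochs=4), tiny_splits, TINY_SPEC)
        assert rec.stopped_epoch <= 4
        assert rec.convergence_epoch <= rec.stopped_epoch
        assert np.all(np.isfinite(rec.epochs["train_loss_weighted"]))
        assert 0.0 <= rec.test_dice <= 1.0

    def test_gradient_isolation_of_weights(self, tiny_splits):
        """Supplying the same numeric weights as constants reproduces the
        entropy-UAT update exactly: no derivative path through U."""
        from uatseg.loss import EPS
        from uatseg.model import build_model
        from uatseg.nn import Adam, sigmoid
        from uatseg.uncertainty import entropy_map

        train = tiny_splits[0]
        x = train[0].image[None, None]
        t = train[0].mask[None].astype(np.float64)
        gamma = 2.0

        def one_step(weight_source):
            model = build_model(SegModelSpec(base_width=4, depth=2, seed=21))
            opt = Adam(model.params, lr=1e-3)
            logits, cache = model.forward(x)
            probs = sigmoid(logits)
            primary = probs.mean(axis=1)
            w_map = weight_source(primary)
            pc = np.clip(primary, EPS, 1 - EPS)
            dterm = -t / pc + (1 - t) / (1 - pc)
            dprimary = w_map * dterm / primary.size
            dlogits = dprimary[:, None] * probs * (1 - probs) / probs.shape[1]
            opt.step(model.backward(dlogits, cache))
            return model.state_dict()

        live = one_step(lambda p: 1.0 + gamma * entropy_map(p))
        frozen_w = 1.0 + gamma * entropy_map(
            sigmoid(build_model(SegModelSpec(base_width=4, depth=2, seed=21))
                    .forward(x)[0]).mean(axis=1))
        const = one_step(lambda p: frozen_w)
        for key in live:
            np.testing.assert_array_equal(live[key], const[key])

    def test_run_directory_artifacts(self, tiny_splits, tmp_path):
        cfg = tiny_config(method="entropy", max_epochs=2)
        run_training(cfg, tiny_splits, TINY_SPEC, out_dir=tmp_path)
        assert (tmp_path / "record.csv").exists()
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / f"run_{cfg.run_seed}_best.npz").exists()
        snaps = tmp_path / "snapshots"
        assert (snaps / "epoch_1_train_pred.png").exists()
        assert (snaps / "epoch_1_val_unc.tif").exists()
        assert (snaps / "epoch_2_train_unc.png").exists()
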