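"""Unit and property tests for the uncertainty maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uatseg import (
    LN2,
    ConformalCalibration,
    ConformalCalibrator,
    conformal_map,
    conformal_quantile,
    entropy_map,
    lac_scores,
    prediction_sets,
    save_uncertainty_png,
    save_uncertainty_tiff,
    variance_map,
)

ALPHA_GRID = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


def sort_index_quantile(scores, alpha):
    """Independent sort-then-index oracle for the conformal quantile."""
    s = sorted(scores)
    n = len(s)
    k = math.ceil((1 - alpha) * (n + 1))
    return 1.0 if k > n else s[k - 1]


class TestEntropy:
    @pytest.mark.parametrize("p,expected", [
        (0.5, math.log(2)),
        (0.0, 0.0),
        (1.0, 0.0),
        (0.9, -0.9 * math.log(0.9) - 0.1 * math.log(0.1)),
    ])
    def test_scalar_values(self, p, expected):
        assert entropy_map(np.array([p]))[0] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        p = rng.random((40, 40))
        u = entropy_map(p)
        np.testing.assert_allclose(u, entropy_map(1 - p), atol=1e-12)
        assert np.all(u >= 0) and np.all(u <= LN2 + 1e-15)

    def test_maximum_only_at_half(self):
        p = np.array([0.5, 0.4999, 0.5001, 0.1])
        u = entropy_map(p)
        assert u[0] == pytest.approx(LN2, abs=1e-15)
        assert np.all(u[1:] < LN2)

    @pytest.mark.parametrize("bad", [[-0.1], [1.1], [np.nan], [np.inf]])
    def test_rejects_invalid_probabilities(self, bad):
        with pytest.raises(ValueError):
            entropy_map(np.array(bad))


class TestLacScores:
    def test_definition(self):
        probs = np.array([0.8, 1.0, 0.3])
        truth = np.array([1, 1, 0])
        np.testing.assert_allclose(lac_scores(probs, truth), [0.2, 0.0, 0.3],
                                   atol=1e-15)

    def test_two_class_oracle(self):
        # explicit (p0, p1) pair: the score is one minus the true class prob
        rng = np.random.default_rng(1)
        p = rng.random(200)
        y = rng.integers(0, 2, 200)
        pair = np.stack([1 - p, p])
        expected = 1 - pair[y, np.arange(200)]
        np.testing.assert_allclose(lac_scores(p, y), expected, atol=1e-15)

    def test_errors(self):
        with pytest.raises(ValueError):
            lac_scores(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            lac_scores(np.zeros(3), np.array([0, 1, 2]))


class TestConformalQuantile:
    def test_examples(self):
        calib = conformal_quantile(np.arange(0.1, 0.95, 0.1), alpha=0.5)
        assert calib.q_hat == pytest.approx(0.5)
        assert calib.n_cal == 9
        assert conformal_quantile(np.array([0.2, 0.4, 0.6, 0.8]), 0.1).q_hat == 1.0
        assert conformal_quantile(np.array([0.3]), 0.5).q_hat == pytest.approx(0.3)

    def test_matches_sort_index_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 501))
            scores = rng.random(n)
            for alpha in ALPHA_GRID:
                got = conformal_quantile(scores, alpha).q_hat
                assert got == sort_index_quantile(scores, alpha)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        scores = rng.random(137)
        qs = [conformal_quantile(scores, a).q_hat for a in ALPHA_GRID]
        assert all(q1 >= q2 for q1, q2 in zip(qs, qs[1:]))

    def test_accepts_list_of_arrays(self):
        parts = [np.array([0.1, 0.2]), np.array([0.3])]
        pooled = conformal_quantile(parts, 0.5)
        assert pooled.n_cal == 3
        assert pooled.q_hat == sort_index_quantile([0.1, 0.2, 0.3], 0.5)

    def test_subsampling_is_seeded(self):
        rng = np.random.default_rng(4)
        scores = rng.random(5000)
        a = conformal_quantile(scores, 0.2, seed=7, max_pool=1000)
        b = conformal_quantile(scores, 0.2, seed=7, max_pool=1000)
        assert a.q_hat == b.q_hat and a.n_cal == 1000

    def test_errors(self):
        with pytest.raises(ValueError):
            conformal_quantile(np.array([]), 0.1)
        for alpha in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                conformal_quantile(np.array([0.5]), alpha)


class TestConformalMap:
    def test_singleton_set(self):
        calib = ConformalCalibration(alpha=0.3, n_cal=10, q_hat=0.3)
        u = conformal_map(np.array([[0.2]]), calib)  # (p0, p1) = (0.8, 0.2)
        assert u[0, 0] == 0.0

    def test_full_set(self):
        calib = ConformalCalibration(alpha=0.3, n_cal=10, q_hat=0.6)
        assert conformal_map(np.array([[0.5]]), calib)[0, 0] == 1.0

    def test_maximal_quantile_everywhere_uncertain(self):
        calib = ConformalCalibration(alpha=0.1, n_cal=2, q_hat=1.0)
        u = conformal_map(np.random.default_rng(0).random((8, 8)), calib)
        assert np.all(u == 1.0)

    def test_binary_output(self):
        calib = ConformalCalibration(alpha=0.2, n_cal=50, q_hat=0.35)
        u = conformal_map(np.random.default_rng(1).random((16, 16)), calib)
        assert set(np.unique(u)) <= {0.0, 1.0}

    def test_unfitted_calibrator_raises(self):
        with pytest.raises(RuntimeError):
            ConformalCalibrator(alpha=0.1).transform(np.array([[0.5]]))


class TestMarginalCoverage:
    @pytest.mark.parametrize("alpha", ALPHA_GRID)
    def test_coverage_guarantee(self, alpha):
        """Exchangeable calibration/test draws: the true class lands in the
        prediction set at least 1 - alpha - 0.02 of the time."""
        coverages = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            p_cal = rng.beta(2, 2, size=2000)
            y_cal = (rng.random(2000) < p_cal).astype(int)
            calib = conformal_quantile(lac_scores(p_cal, y_cal), alpha)
            p_test = rng.beta(2, 2, size=2000)
            y_test = (rng.random(2000) < p_test).astype(int)
            in0, in1 = prediction_sets(p_test, calib)
            covered = np.where(y_test == 1, in1, in0)
            coverages.append(covered.mean())
        assert np.mean(coverages) >= 1 - alpha - 0.02


class TestVariance:
    def test_examples(self):
        assert variance_map([np.full((2, 2), 0.7)] * 3).max() == 0.0
        u = variance_map([np.array([[0.0]]), np.array([[0.5]]), np.array([[1.0]])])
        assert u[0, 0] == pytest.approx(1 / 6, abs=1e-12)
        u2 = variance_map([np.array([[0.0]]), np.array([[1.0]])])
        assert u2[0, 0] == pytest.approx(0.25, abs=1e-15)

    def test_scalar_loop_oracle(self):
        rng = np.random.default_rng(5)
        maps = [rng.random((6, 7)) for _ in range(4)]
        got = variance_map(maps)
        for i in range(6):
            for j in range(7):
                vals = [m[i, j] for m in maps]
                mean = sum(vals) / 4
                expected = sum((v - mean) ** 2 for v in vals) / 4
                assert got[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_quarter(self):
        rng = np.random.default_rng(6)
        u = variance_map([rng.random((10, 10)) for _ in range(5)])
        assert np.all(u >= 0) and np.all(u <= 0.25 + 1e-15)

    def test_errors(self):
        with pytest.raises(ValueError):
            variance_map([np.zeros((2, 2))])
        with pytest.raises(ValueError):
            variance_map([np.zeros((2, 2)), np.zeros((3, 3))])


class TestCalibratorEstimator:
    def test_fit_transform_and_sklearn_params(self):
        rng = np.random.default_rng(7)
        probs = [rng.random((8, 8)) for _ in range(3)]
        masks = [(rng.random((8, 8)) < 0.5).astype(int) for _ in range(3)]
        cal = ConformalCalibrator(alpha=0.2).fit(probs, masks)
        assert cal.n_cal_ == 3 * 64
        u = cal.transform(rng.random((8, 8)))
        assert set(np.unique(u)) <= {0.0, 1.0}
        assert cal.get_params()["alpha"] == 0.2
        cal.set_params(alpha=0.1)
        assert cal.alpha == 0.1

    def test_calibration_json_round_trip(self):
        calib = ConformalCalibration(alpha=0.15, n_cal=123, q_hat=0.42, seed=9)
        assert ConformalCalibration.from_json(calib.to_json()) == calib


class TestExports:
    def test_tiff_round_trip(self, tmp_path):
        import tifffile

        u = np.random.default_rng(8).random((12, 12))
        path = tmp_path / "u.tif"
        save_uncertainty_tiff(u, path)
        back = tifffile.imread(path)
        assert back.dtype == np.float32
        np.testing.assert_allclose(back, u, atol=1e-6)

    def test_png_heatmap_rescaled(self, tmp_path):
        from PIL import Image

        u = np.array([[0.0, LN2 / 2], [LN2, LN2]])
        path = tmp_path / "u.png"
        save_uncertainty_png(u, path, vmax=LN2)
        arr = np.asarray(Image.open(path))
        assert arr.dtype == np.uint8
        assert arr[0, 0] == 0 and arr[1, 0] == 255 and arr[0, 1] == 128


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50),
       st.floats(min_value=0.01, max_value=0.99))
def test_quantile_always_a_score_or_one(scores, alpha):
    q = conformal_quantile(np.array(scores), alpha).q_hat
    assert q == 1.0 or any(abs(q - s) < 1e-15 for s in scores)
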