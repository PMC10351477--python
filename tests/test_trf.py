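"""Boosted TRF estimation: folds, prediction, smoothing, kernel recovery."""

import numpy as np
import pytest

from neurotrack.trf import (
    BoostingTRF,
    crossval_trf,
    lag_samples,
    lagged_design,
    make_folds,
    predict_eeg,
    prediction_accuracy,
    smooth_basis,
)

FS = 128.0
LAGS = lag_samples(FS)


class TestFolds:
    def test_even_split(self):
        folds = make_folds(100, 10)
        assert [s.stop - s.start for s in folds.segments] == [10] * 10

    def test_remainder_distribution(self):
        folds = make_folds(101, 10)
        lengths = sorted(s.stop - s.start for s in folds.segments)
        assert lengths == [10] * 9 + [11]

    def test_rotations_partition_and_cover(self):
        folds = make_folds(97, 10)
        covered = np.zeros(97, dtype=int)
        for train, val, test in folds.rotations():
            assert set(train) | {val, test} == set(range(10))
            assert val != test
            seg = folds.segments[test]
            covered[seg] += 1
        assert np.all(covered == 1)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, 10)


class TestPredictEEG:
    def test_zero_kernels_give_zero(self, rng):
        x = rng.standard_normal((2, 300))
        pred = predict_eeg(np.zeros((2, len(LAGS), 3)), x, LAGS)
        assert np.all(pred == 0)

    def test_impulse_places_kernel_with_acausal_part(self, rng):
        T = 300
        s = 150
        x = np.zeros((1, T))
        x[0, s] = 1.0
        kern = rng.standard_normal((1, len(LAGS), 1))
        pred = predict_eeg(kern, x, LAGS)[0]
        np.testing.assert_allclose(pred[s - 12: s + 77], kern[0, :, 0], atol=1e-12)
        assert np.all(pred[: s - 12] == 0)

    def test_matches_brute_force_convolution(self, rng):
        x = rng.standard_normal((2, 120))
        kern = rng.standard_normal((2, len(LAGS), 2))
        pred = predict_eeg(kern, x, LAGS)
        expected = np.zeros_like(pred)
        for c in range(2):
            for t in range(120):
                acc = 0.0
                for p in range(2):
                    for j, lag in enumerate(LAGS):
                        if 0 <= t - lag < 120:
                            acc += kern[p, j, c] * x[p, t - lag]
                expected[c, t] = acc
        np.testing.assert_allclose(pred, expected, atol=1e-9)

    def test_linear_in_kernels_and_features(self, rng):
        x = rng.standard_normal((1, 200))
        k1 = rng.standard_normal((1, len(LAGS), 1))
        k2 = rng.standard_normal((1, len(LAGS), 1))
        np.testing.assert_allclose(
            predict_eeg(k1 + 2 * k2, x, LAGS),
            predict_eeg(k1, x, LAGS) + 2 * predict_eeg(k2, x, LAGS),
            atol=1e-10,
        )


class TestPredictionAccuracy:
    def test_perfect_and_inverted(self, rng):
        y = rng.standard_normal((3, 100))
        np.testing.assert_allclose(prediction_accuracy(y, y), 1.0)
        np.testing.assert_allclose(prediction_accuracy(-y, y), -1.0)

    def test_independent_signals_near_zero(self, rng):
        a = rng.standard_normal((1, 5000))
        b = rng.standard_normal((1, 5000))
        assert abs(prediction_accuracy(a, b)[0]) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            prediction_accuracy(np.ones((1, 10)), np.random.default_rng(0).random((1, 10)))


class TestBasisSmoothing:
    def test_delta_becomes_hamming_bump(self):
        kern = np.zeros((1, 89, 1))
        kern[0, 44, 0] = 1.0
        out = smooth_basis(kern, FS)
        assert out[0, 44, 0] == out[0].max()
        assert np.count_nonzero(out[0, :, 0]) in (6, 7)

    def test_mass_preserved(self, rng):
        kern = rng.standard_normal((3, 89, 4))
        out = smooth_basis(kern, FS)
        np.testing.assert_allclose(
            out.sum(axis=1), kern.sum(axis=1), atol=1e-9
        )

    def test_two_separated_deltas_stay_separated(self):
        kern = np.zeros((1, 89, 1))
        kern[0, 20, 0] = 1.0
        kern[0, 46, 0] = 1.0  # ~200 ms apart
        out = smooth_basis(kern, FS)[0, :, 0]
        assert np.all(out[30:40] == 0)

    def test_window_longer_than_axis_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            smooth_basis(np.zeros((1, 4, 1)), FS, window_s=0.2)


class TestBoosting:
    def test_noiseless_delta_kernel_recovered_at_100ms(self, rng):
        T = 60 * 128
        x = np.zeros((1, T))
        x[0, rng.choice(T, 200, replace=False)] = 1.0
        lag_idx = np.argmin(np.abs(LAGS / FS * 1000 - 100.0))
        kern = np.zeros((1, len(LAGS), 1))
        kern[0, lag_idx, 0] = 1.0
        y = predict_eeg(kern, x, LAGS)
        est = BoostingTRF(fs=FS).fit(x.T, y.T)
        got = np.argmax(np.abs(est.kernels_[0, :, 0]))
        assert abs(got - lag_idx) <= 1

    def test_zero_feature_gives_zero_kernel(self, rng):
        x = np.zeros((1, 2000))
        y = rng.standard_normal((1, 2000))
        est = BoostingTRF(fs=FS, scale_features=False).fit(x.T, y.T)
        assert np.all(est.kernels_ == 0)

    def test_two_orthogonal_predictors_recovered_at_0db(self, rng):
        T = 120 * 128
        x = np.zeros((2, T))
        # random impulse trains on disjoint samples (orthogonal predictors)
        times = rng.choice(T // 2, size=800, replace=False) * 2
        x[0, times[:400]] = 1.0
        x[1, times[400:] + 1] = 1.0
        lag_ms = LAGS / FS * 1000
        k1 = np.exp(-((lag_ms - 120) ** 2) / (2 * 25 ** 2))
        k2 = -np.exp(-((lag_ms - 300) ** 2) / (2 * 40 ** 2))
        kern = np.stack([k1[:, None], k2[:, None]])
        y = predict_eeg(kern, x, LAGS)
        noise = rng.standard_normal(y.shape) * y.std()  # SNR 0 dB
        est = BoostingTRF(fs=FS).fit(x.T, (y + noise).T)
        for p, truth in enumerate((k1, k2)):
            r = np.corrcoef(est.kernels_[p, :, 0], truth)[0, 1]
            assert r >= 0.9

    def test_scale_equivariance_in_eeg(self, rng):
        T = 4000
        x = (rng.random((1, T)) < 0.03).astype(float)
        kern = np.zeros((1, len(LAGS), 1))
        kern[0, 30, 0] = 1.0
        y = predict_eeg(kern, x, LAGS) + 0.3 * rng.standard_normal((1, T))
        a = BoostingTRF(fs=FS).fit(x.T, y.T).kernels_
        b = BoostingTRF(fs=FS).fit(x.T, (5.0 * y).T).kernels_
        np.testing.assert_allclose(b, 5.0 * a, rtol=1e-9, atol=1e-12)

    def test_constant_channel_warns_and_zeroes(self, rng):
        x = (rng.random((1, 2000)) < 0.05).astype(float)
        y = np.vstack([rng.standard_normal(2000), np.full(2000, 2.0)])
        with pytest.warns(UserWarning, match="constant"):
            est = BoostingTRF(fs=FS).fit(x.T, y.T)
        assert np.all(est.kernels_[:, :, 1] == 0)


class TestCrossval:
    def _planted(self, rng, T=100 * 128, snr_db=-6.0):
        x = (rng.random((1, T)) < 0.027).astype(float)
        lag_ms = LAGS / FS * 1000
        k = np.exp(-((lag_ms - 150) ** 2) / (2 * 30 ** 2))
        kern = k[:, None][None, :, :]
        y = predict_eeg(kern, x, LAGS)
        noise = rng.standard_normal(y.shape)
        y = y + noise * y.std() / noise.std() * 10 ** (-snr_db / 20)
        return x, y, k

    def test_fold_accuracy_bookkeeping(self, rng):
        x, y, _ = self._planted(rng)
        model = crossval_trf(x, y, k=10, fs=FS)
        assert model.fold_accuracies.shape == (10, 1)
        assert model.kernels.shape == (1, len(LAGS), 1)

    def test_planted_kernel_gives_positive_heldout_accuracy(self, rng):
        import scipy.stats

        x, y, k = self._planted(rng)
        model = crossval_trf(x, y, k=10, fs=FS)
        res = scipy.stats.wilcoxon(model.fold_accuracies[:, 0])
        assert model.mean_accuracy[0] > 0
        assert res.pvalue < 0.01
        assert np.corrcoef(model.kernels[0, :, 0], k)[0, 1] > 0.8

    def test_circularly_shifted_control_near_zero(self, rng):
        x, y, _ = self._planted(rng)
        y_shift = np.roll(y, 20 * 128, axis=1)
        model = crossval_trf(x, y_shift, k=10, fs=FS)
        assert abs(model.mean_accuracy[0]) < 0.05


class TestEstimatorContract:
    def test_get_set_params_roundtrip(self):
        est = BoostingTRF(delta=0.01)
        params = est.get_params()
        assert params["delta"] == 0.01
        est2 = BoostingTRF().set_params(**params)
        assert est2.delta == 0.01

    def test_predict_and_score(self, rng):
        T = 5000
        x = (rng.random((1, T)) < 0.03).astype(float)
        kern = np.zeros((1, len(LAGS), 1))
        kern[0, 40, 0] = 1.0
        y = predict_eeg(kern, x, LAGS)
        est = BoostingTRF(fs=FS).fit(x.T, y.T)
        pred = est.predict(x.T)
        assert pred.shape == (T, 1)
        assert est.score(x.T, y.T) > 0.95
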