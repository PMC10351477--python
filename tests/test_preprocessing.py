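"""EEG preprocessing chain and denoising source separation."""

import numpy as np
import pytest
import scipy.signal

from neurotrack.containers import EEGRecording
from neurotrack.preprocessing import (
    DSS,
    apply_bandpass,
    common_average_reference,
    design_ls_bandpass,
    preprocess,
    truncate,
    zscore_across_conditions,
)


def _combined_response(filt, fs, freqs):
    hp, lp = filt
    w, h1 = scipy.signal.freqz(hp, worN=freqs, fs=fs)
    _, h2 = scipy.signal.freqz(lp, worN=freqs, fs=fs)
    return np.abs(h1 * h2)


def make_rec(data, fs=128.0, cond="c"):
    labels = tuple(f"CH{i}" for i in range(data.shape[0]))
    return EEGRecording(data=data, fs=fs, channel_labels=labels, condition_id=cond)


class TestBandpassDesign:
    def test_passband_flat_at_10hz(self, bandpass_256):
        mag = _combined_response(bandpass_256, 256.0, np.array([10.0]))[0]
        assert abs(20 * np.log10(mag)) < 0.5

    def test_stopbands_suppressed(self, bandpass_256):
        mags = _combined_response(bandpass_256, 256.0, np.array([1e-3, 40.0]))
        assert 20 * np.log10(mags[0]) <= -30
        assert 20 * np.log10(mags[1]) <= -30

    def test_10hz_sinusoid_amplitude_preserved(self, bandpass_256):
        fs = 256.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        y = apply_bandpass(x, bandpass_256)
        core = y[int(12 * fs): int(18 * fs)]
        amp = (core.max() - core.min()) / 2
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_30hz_attenuated_20db(self, bandpass_256):
        fs = 256.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 30.0 * t)
        y = apply_bandpass(x, bandpass_256)[int(12 * fs): int(18 * fs)]
        assert 20 * np.log10(np.abs(y).max()) <= -20

    def test_too_low_fs_rejected(self):
        with pytest.raises(ValueError):
            design_ls_bandpass(40.0)


class TestCARandZscore:
    def test_car_zero_mean_per_sample(self, rng):
        data = rng.standard_normal((16, 1000))
        out = common_average_reference(data)
        assert np.abs(out.mean(axis=0)).max() < 1e-10

    def test_car_removes_common_offset(self, rng):
        data = rng.standard_normal((8, 500))
        offset = rng.standard_normal(500)
        np.testing.assert_allclose(
            common_average_reference(data + offset),
            common_average_reference(data),
            atol=1e-12,
        )

    def test_zscore_single_condition(self, rng):
        rec = make_rec(3.0 * rng.standard_normal((4, 2000)) + 5.0)
        (out,) = zscore_across_conditions([rec])
        assert np.abs(out.data.mean(axis=1)).max() < 1e-9
        np.testing.assert_allclose(out.data.std(axis=1), 1.0, atol=1e-9)

    def test_zscore_across_three_conditions(self, rng):
        recs = [make_rec(rng.standard_normal((4, 500)) + i, cond=f"c{i}") for i in range(3)]
        outs = zscore_across_conditions(recs)
        concat = np.concatenate([o.data for o in outs], axis=1)
        assert np.abs(concat.mean(axis=1)).max() < 1e-9
        np.testing.assert_allclose(concat.std(axis=1), 1.0, atol=1e-9)
        # individual conditions keep their offsets relative to the pool
        assert abs(outs[0].data.mean()) > 0.1

    def test_zscore_scale_invariance(self, rng):
        data = rng.standard_normal((4, 800))
        (a,) = zscore_across_conditions([make_rec(data)])
        scaled = data.copy()
        scaled[2] *= 7.0
        (b,) = zscore_across_conditions([make_rec(scaled)])
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_zero_variance_channel_named(self, rng):
        data = rng.standard_normal((3, 100))
        data[1] = 4.2
        with pytest.raises(ValueError, match="CH1"):
            zscore_across_conditions([make_rec(data)])


class TestTruncate:
    def test_455s_at_128hz_is_58240_samples(self, rng):
        rec = make_rec(rng.standard_normal((2, 500 * 128)))
        out = truncate(rec, 455.0)
        assert out.n_samples == 455 * 128 == 58240

    def test_idempotent(self, rng):
        rec = make_rec(rng.standard_normal((2, 500 * 128)))
        once = truncate(rec, 100.0)
        twice = truncate(once, 100.0)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_short_recording_rejected(self, rng):
        rec = make_rec(rng.standard_normal((2, 128)))
        with pytest.raises(ValueError, match="shorter"):
            truncate(rec, 455.0)


class TestPreprocessChain:
    def test_chain_outputs_128hz_with_provenance(self, rng):
        fs = 512.0
        rec = make_rec(rng.standard_normal((8, int(20 * fs))), fs=fs)
        out = preprocess(rec)
        assert out.fs == 128.0
        steps = ";".join(out.meta)
        for step in ("resample", "car", "bandpass"):
            assert step in steps

    def test_30hz_component_attenuated(self, rng):
        fs = 512.0
        t = np.arange(int(20 * fs)) / fs
        data = 0.01 * rng.standard_normal((4, t.size))
        data[2] += np.sin(2 * np.pi * 30.0 * t)
        out = preprocess(make_rec(data, fs=fs))
        mid = out.data[:, out.n_samples // 4: -out.n_samples // 4]
        f, psd = scipy.signal.welch(mid[2], fs=128.0, nperseg=512)
        band = psd[(f > 28) & (f < 32)].mean()
        ref = np.sin(2 * np.pi * 30.0 * np.arange(int(10 * 128)) / 128.0)
        f0, psd0 = scipy.signal.welch(ref, fs=128.0, nperseg=512)
        assert 10 * np.log10(band / psd0[(f0 > 28) & (f0 < 32)].mean()) < -20

    def test_low_rate_input_rejected(self, rng):
        with pytest.raises(ValueError):
            preprocess(make_rec(rng.standard_normal((2, 1000)), fs=128.0))


class TestDSS:
    def _planted(self, rng, n_rec=10, C=64, T=int(60 * 128), amp=1.0):
        t = np.arange(T) / 128.0
        sig = np.sin(2 * np.pi * 5.0 * t)
        topo = rng.standard_normal(C)
        recs = [amp * topo[:, None] * sig[None, :] + rng.standard_normal((C, T))
                for _ in range(n_rec)]
        return recs, sig

    def test_planted_component_recovered(self, rng):
        recs, sig = self._planted(rng)
        dss = DSS().fit(recs, fs=128.0)
        comp1 = dss.to_components_[0] @ recs[0]
        assert abs(np.corrcoef(comp1, sig)[0, 1]) >= 0.9

    def test_projection_idempotent_and_rank_bounded(self, rng):
        recs, _ = self._planted(rng, C=16)
        dss = DSS(n_components=6).fit(recs, fs=128.0)
        p1 = dss.transform(recs[0])
        p2 = dss.transform(p1)
        assert np.abs(p1 - p2).max() < 1e-8
        assert np.linalg.matrix_rank(p1, tol=1e-6) <= 6

    def test_full_rank_roundtrip_is_identity(self, rng):
        recs, _ = self._planted(rng, C=8, T=2000)
        dss = DSS().fit(recs, fs=128.0)
        out = dss.transform(recs[0], k=8)
        np.testing.assert_allclose(out, recs[0], atol=1e-8)

    def test_null_power_ratios_near_one(self, rng):
        recs = [rng.standard_normal((16, int(60 * 128))) for _ in range(10)]
        dss = DSS().fit(recs, fs=128.0)
        assert np.all(dss.power_ratios_ > 0.5)
        assert np.all(dss.power_ratios_ < 2.0)

    def test_identical_recordings_ratio_equals_count(self, rng):
        X = rng.standard_normal((6, 4000))
        dss = DSS().fit([X.copy() for _ in range(4)], fs=128.0)
        np.testing.assert_allclose(dss.power_ratios_, 4.0, rtol=1e-6)

    def test_planted_signal_survives_projection(self, rng):
        recs, sig = self._planted(rng)
        dss = DSS(n_components=6).fit(recs, fs=128.0)
        proj = dss.transform(recs[0])
        best = max(abs(np.corrcoef(proj[c], sig)[0, 1]) for c in range(proj.shape[0]))
        assert best >= 0.9
        assert proj.var() < recs[0].var()

    def test_channel_mismatch_rejected(self, rng):
        recs, _ = self._planted(rng, C=8, T=2000)
        dss = DSS().fit(recs, fs=128.0)
        with pytest.raises(ValueError, match="channel"):
            dss.transform(rng.standard_normal((9, 2000)))

    def test_single_recording_rejected(self, rng):
        with pytest.raises(ValueError, match="two"):
            DSS().fit([rng.standard_normal((4, 1000))], fs=128.0)
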