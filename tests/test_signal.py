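import numpy as np
import pandas as pd
import pytest
import scipy.signal

from asme.signal import (
    Epochs,
    FilterSpec,
    bandpass,
    extract_epochs,
    fit_pca_ica,
    interval_means,
    pick_eog_components,
    remove_components,
    resample,
)
from asme.synth import Recording


def _rec(data, fs=250.0, onsets=(), **meta):
    labels = [f"ch{i}" for i in range(data.shape[0])]
    events = pd.DataFrame(
        {"onset_s": list(onsets), "is_target": [False] * len(onsets), **meta}
    )
    return Recording(np.asarray(data, float), fs, labels, events)


class TestBandpass:
    def test_dc_rejected(self):
        fs = 250.0
        rec = _rec(np.full((1, int(6 * fs)), 5.0), fs)
        out = bandpass(rec, FilterSpec(1.0, 40.0)).data[0]
        assert np.max(np.abs(out[int(2 * fs):])) < 0.05  # <1% of DC input

    @pytest.mark.parametrize("freq, fs", [(5.0, 250.0), (80.0, 1000.0)])
    def test_sinusoid_gain_matches_design_response(self, freq, fs):
        # oracle: evaluate the designed filter's frequency response at freq
        spec = FilterSpec(1.0, 40.0)
        t = np.arange(int(10 * fs)) / fs
        rec = _rec(np.sin(2 * np.pi * freq * t)[None, :], fs)
        out = bandpass(rec, spec).data[0]
        steady = out[int(5 * fs):]
        measured = (steady.max() - steady.min()) / 2
        sos = scipy.signal.butter(2, [1.0, 40.0], btype="bandpass", fs=fs, output="sos")
        _, h = scipy.signal.sosfreqz(sos, worN=[freq], fs=fs)
        assert measured == pytest.approx(np.abs(h[0]), rel=0.02)
        if freq == 5.0:
            assert abs(measured - 1.0) < 0.05  # passband
        else:
            assert measured < 0.3  # stopband

    def test_causality_no_precursor(self):
        fs = 250.0
        x = np.zeros((1, int(4 * fs)))
        x[0, int(2 * fs)] = 1.0
        out = bandpass(_rec(x, fs)).data[0]
        assert np.all(out[: int(2 * fs)] == 0)

    def test_linearity(self, rng):
        fs = 250.0
        x = rng.standard_normal((2, 1000))
        y = rng.standard_normal((2, 1000))
        fx = bandpass(_rec(x, fs)).data
        fy = bandpass(_rec(y, fs)).data
        fxy = bandpass(_rec(2 * x + 3 * y, fs)).data
        np.testing.assert_allclose(fxy, 2 * fx + 3 * fy, atol=1e-10)

    def test_cutoff_validation(self):
        rec = _rec(np.zeros((1, 100)), fs=100.0)
        with pytest.raises(ValueError):
            bandpass(rec, FilterSpec(1.0, 60.0))
        with pytest.raises(ValueError):
            bandpass(rec, FilterSpec(40.0, 1.0))


class TestExtractEpochs:
    def test_sample_count_convention(self):
        fs = 1000.0
        onsets = 1.0 + 0.2 * np.arange(450)
        rec = _rec(np.zeros((2, int(120 * fs))), fs, onsets)
        ep = extract_epochs(rec, tmin_s=-0.1, tmax_s=1.0)
        assert ep.data.shape == (450, 2, 1100)  # round((1.0 - (-0.1)) * 1000)

    def test_zero_padding_past_run_end(self):
        fs = 100.0
        data = np.ones((1, int(3 * fs)))
        rec = _rec(data, fs, onsets=[2.5])  # 0.5 s before run end
        ep = extract_epochs(rec, tmin_s=0.0, tmax_s=2.1)
        epoch = ep.data[0, 0]
        assert np.all(epoch[: int(0.5 * fs)] == 1.0)
        assert np.all(epoch[int(0.5 * fs):] == 0.0)

    def test_no_events_gives_empty_container(self):
        rec = _rec(np.zeros((3, 1000)), 250.0)
        ep = extract_epochs(rec, tmin_s=-0.1, tmax_s=1.0)
        assert len(ep) == 0 and ep.data.shape[1] == 3

    def test_order_preserved_and_tmin_validation(self):
        fs = 100.0
        rec = _rec(np.arange(1000, dtype=float)[None, :], fs, onsets=[5.0, 1.0])
        ep = extract_epochs(rec, tmin_s=0.0, tmax_s=0.1)
        assert ep.data[0, 0, 0] == 500 and ep.data[1, 0, 0] == 100
        with pytest.raises(ValueError):
            extract_epochs(rec, tmin_s=1.0, tmax_s=1.0)


class TestResample:
    def _epochs(self, fs, tmin, tmax, n_ev=3, n_ch=2, fill=None, rng=None):
        n = int(round((tmax - tmin) * fs))
        data = (rng or np.random.default_rng(0)).standard_normal((n_ev, n_ch, n))
        if fill is not None:
            data = np.broadcast_to(fill, (n_ev, n_ch, n)).copy()
        md = pd.DataFrame({"is_target": [False] * n_ev})
        return Epochs(data, tmin, tmax, fs, [f"c{i}" for i in range(n_ch)], md)

    def test_sample_count_1000_to_128(self):
        ep = self._epochs(1000.0, -0.1, 2.1)
        out = resample(ep, 128.0)
        assert out.data.shape[2] == 282  # round(2.2 * 128)
        assert out.fs_hz == 128.0
        assert out.metadata.equals(ep.metadata)

    def test_identity_when_rates_match(self):
        ep = self._epochs(250.0, -0.1, 1.0)
        assert resample(ep, 250.0) is ep

    def test_tone_amplitude_preserved(self):
        fs = 250.0
        t = np.arange(int(4 * fs)) / fs
        data = np.sin(2 * np.pi * 5.0 * t)[None, None, :]
        ep = Epochs(data, 0.0, 4.0, fs, ["c0"], pd.DataFrame({"is_target": [False]}))
        out = resample(ep, 128.0).data[0, 0]
        mid = out[out.size // 4 : -out.size // 4]  # avoid edge transients
        assert (mid.max() - mid.min()) / 2 == pytest.approx(1.0, rel=0.02)

    def test_invalid_rates(self):
        ep = self._epochs(250.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            resample(ep, -1.0)
        with pytest.raises(ValueError):
            resample(ep, 500.0)


class TestIntervalMeans:
    def _epochs(self, data, fs, tmin, tmax, labels=None):
        n_ev, n_ch, _ = data.shape
        md = pd.DataFrame({"is_target": [False] * n_ev})
        labels = labels or [f"c{i}" for i in range(n_ch)]
        return Epochs(np.asarray(data, float), tmin, tmax, fs, labels, md)

    def test_640_features_for_64_channels(self, rng):
        fs = 1000.0
        data = rng.standard_normal((5, 64, int(1.1 * fs)))
        ep = self._epochs(data, fs, -0.1, 1.0)
        fm = interval_means(ep, 0.0, 1.0, 0.1)
        assert fm.values.shape == (5, 640)
        assert len(fm.feature_names) == 640

    def test_constant_signal_gives_constant_features(self):
        ep = self._epochs(np.full((2, 3, 110), 2.5), 100.0, -0.1, 1.0)
        fm = interval_means(ep, 0.0, 1.0)
        assert np.all(fm.values == 2.5)

    def test_block_average_oracle(self):
        # one channel equal to the sample index at fs 100; bin [0, 0.1) holds
        # samples 0..9 so the feature is their mean
        data = np.arange(10, dtype=float)[None, None, :]
        ep = self._epochs(data, 100.0, 0.0, 0.1)
        fm = interval_means(ep, 0.0, 0.1, 0.1)
        assert fm.values[0, 0] == pytest.approx(np.mean(np.arange(10)))

    def test_noninteger_bin_counts_at_128hz(self, rng):
        # 0.1 s at 128 Hz is 12.8 samples: bins must partition by time
        n = round(1.1 * 128)
        ep = self._epochs(rng.standard_normal((4, 2, n)), 128.0, -0.1, 1.0)
        fm = interval_means(ep, 0.0, 1.0, 0.1)
        assert fm.values.shape == (4, 20)
        # mean of bin means weighted by bin occupancy == overall mean
        t = ep.times
        mask = (t >= -1e-9) & (t < 1.0 - 1e-9)
        overall = ep.data[..., mask].mean(axis=2)
        k = np.floor((t[mask]) / 0.1 + 1e-9).astype(int)
        w = np.bincount(k, minlength=10) / mask.sum()
        recon = (fm.values.reshape(4, 2, 10) * w).sum(axis=2)
        np.testing.assert_allclose(recon, overall, atol=1e-12)

    def test_channel_permutation_permutes_feature_blocks(self, rng):
        data = rng.standard_normal((3, 4, 100))
        ep = self._epochs(data, 100.0, 0.0, 1.0)
        fm = interval_means(ep, 0.0, 1.0)
        perm = [2, 0, 3, 1]
        ep_p = self._epochs(data[:, perm], 100.0, 0.0, 1.0)
        fm_p = interval_means(ep_p, 0.0, 1.0)
        blocks = fm.values.reshape(3, 4, 10)
        np.testing.assert_array_equal(fm_p.values.reshape(3, 4, 10), blocks[:, perm])

    def test_invalid_windows_rejected(self, rng):
        ep = self._epochs(rng.standard_normal((1, 1, 110)), 100.0, -0.1, 1.0)
        with pytest.raises(ValueError):
            interval_means(ep, 0.0, 1.05, 0.1)  # non-integral bin count
        with pytest.raises(ValueError):
            interval_means(ep, -0.5, 1.0, 0.1)  # outside epoch window


class TestEogSelectionRemoval:
    def test_planted_component_selected(self, rng):
        n = 5000
        eog = np.cumsum(rng.standard_normal(n))
        sources = rng.standard_normal((6, n))
        sources[3] = eog + 0.05 * rng.standard_normal(n)
        assert pick_eog_components(sources, eog[None, :]) == {3}

    def test_two_eog_channels_same_source_deduplicated(self, rng):
        n = 2000
        s = rng.standard_normal((4, n))
        eogs = np.vstack([s[1] + 0.01 * rng.standard_normal(n),
                          s[1] + 0.01 * rng.standard_normal(n)])
        assert pick_eog_components(s, eogs) == {1}

    def test_tie_breaks_to_lowest_index(self):
        x = np.sin(np.linspace(0, 10, 500))
        sources = np.vstack([x, x])  # identical |r| for both
        assert pick_eog_components(sources, x[None, :]) == {0}

    def test_zero_variance_warns(self):
        sources = np.vstack([np.zeros(100), np.arange(100.0)])
        with pytest.warns(UserWarning):
            pick_eog_components(sources, np.arange(100.0)[None, :])

    def test_removal_identity_all_and_planted(self, rng):
        n_ch, n = 4, 3000
        mixing, _ = np.linalg.qr(rng.standard_normal((n_ch, n_ch)))  # orthogonal
        sources = rng.standard_normal((n_ch, n))
        sources[2] = 40.0 * np.sin(np.linspace(0, 60, n))  # planted artifact
        rec = _rec(mixing @ sources, 250.0)
        unmix = mixing.T
        out_none = remove_components(rec, unmix, mixing, set())
        np.testing.assert_allclose(out_none.data, rec.data, atol=1e-10)
        out_all = remove_components(rec, unmix, mixing, set(range(n_ch)))
        assert np.allclose(out_all.data, 0.0)
        out = remove_components(rec, unmix, mixing, {2})
        # artifact power removed almost entirely
        resid = out.data - mixing[:, [0, 1, 3]] @ sources[[0, 1, 3]]
        assert np.sum(resid**2) < 0.05 * np.sum((mixing[:, [2]] @ sources[[2]]) ** 2)
        with pytest.raises(IndexError):
            remove_components(rec, unmix, mixing, {9})

    def test_pca_ica_decomposition_recovers_blink(self, rng):
        # end-to-end: decompose a recording with a planted blink-like source,
        # pick by EOG correlation, remove, and check frontal power drops
        n = 8000
        blink = np.zeros(n)
        for start in range(200, n - 200, 900):
            blink[start : start + 100] += np.hanning(100)
        blink *= 80.0
        base = rng.standard_normal((6, n))
        data = base.copy()
        data[0] += blink
        data[1] += 0.6 * blink
        rec = _rec(data, 250.0)
        unmix, mix = fit_pca_ica(rec.data, n_components=6, seed=0)
        sources = unmix @ rec.data
        picked = pick_eog_components(sources, blink[None, :])
        cleaned = remove_components(rec, unmix, mix, picked)
        assert np.var(cleaned.data[0]) < 0.2 * np.var(rec.data[0])
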