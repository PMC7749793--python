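import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegcomplexity.features import (
    BAND_BY_NAME,
    CANONICAL_BANDS,
    TEConfig,
    bandpass,
    compute_feature_table,
    relative_band_power,
    tsallis_entropy,
    tsallis_entropy_from_probabilities,
)
from eegcomplexity.io import EEGRecording, synthetic_montage

FS = 100.0
THETA = BAND_BY_NAME["theta"]


def _fft_zero_filter(x, lo, hi, fs):
    """Oracle: ideal band-pass by zeroing FFT bins outside [lo, hi]."""
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(len(x), 1 / fs)
    spec[(f < lo) | (f > hi)] = 0
    return np.fft.irfft(spec, n=len(x))


class TestBandpass:
    @pytest.mark.parametrize(
        "freq,expect_pass", [(6.0, True), (20.0, False)]
    )
    def test_tone_attenuation_matches_fft_oracle(self, freq, expect_pass):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass(x, THETA, FS)
        oracle = _fft_zero_filter(x, THETA.lo, THETA.hi, FS)
        ratio = np.sqrt(np.mean(y**2)) / np.sqrt(np.mean(x**2))
        oracle_ratio = np.sqrt(np.mean(oracle**2)) / np.sqrt(np.mean(x**2))
        if expect_pass:
            assert ratio >= 0.95
            assert oracle_ratio >= 0.99
        else:
            assert ratio <= 0.05
            assert oracle_ratio <= 0.01

    def test_zero_signal_gives_zero(self):
        y = bandpass(np.zeros(int(60 * FS)), THETA, FS)
        assert np.allclose(y, 0.0)

    def test_output_length_preserved(self):
        x = np.random.default_rng(0).normal(size=int(30 * FS))
        assert bandpass(x, THETA, FS).shape == x.shape

    def test_zero_phase_inband_tone_peaks_at_lag_zero(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 6.0 * t)
        y = bandpass(x, THETA, FS)
        # cross-correlation at small lags; zero lag must dominate
        lags = range(-5, 6)
        xc = [np.dot(x[5:-5], y[5 + lag : len(y) - 5 + lag]) for lag in lags]
        assert int(np.argmax(xc)) == lags.index(0)

    def test_band_edge_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(10000), BAND_BY_NAME["gamma"], 80.0)


class TestTsallisEntropy:
    def test_constant_signal_is_zero(self):
        for q in (0.5, 2.0, 3.0):
            cfg = TEConfig(q=q)
            assert tsallis_entropy(np.full(5000, 3.7), cfg) == 0.0

    def test_uniform_four_bins_closed_form(self):
        # uniform occupancy of B bins: TE = (1 - B**(1-q)) / (q - 1)
        cfg = TEConfig(q=2.0, n_bins=4)
        te = tsallis_entropy_from_probabilities([0.25] * 4, cfg)
        assert te == pytest.approx(1 - 1 / 4)
        cfg_norm = TEConfig(q=2.0, n_bins=4, normalization="max_entropy")
        assert tsallis_entropy_from_probabilities(
            [0.25] * 4, cfg_norm
        ) == pytest.approx(1.0)

    def test_white_noise_exceeds_sinusoid(self):
        # arcsine amplitude density of a tone piles mass in edge bins
        rng = np.random.default_rng(7)
        n = 100_000
        noise = rng.standard_normal(n)
        tone = np.sqrt(2) * np.sin(2 * np.pi * 7.0 * np.arange(n) / FS)
        cfg = TEConfig(q=2.0, n_bins=100)
        assert tsallis_entropy(noise, cfg) > tsallis_entropy(tone, cfg)

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50_000)
        cfg = TEConfig()
        assert tsallis_entropy(10.0 * x, cfg) == pytest.approx(
            tsallis_entropy(x, cfg), abs=1e-12
        )

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([1.5, 2.0, 3.0]))
    def test_bounds(self, seed, q):
        x = np.random.default_rng(seed).standard_normal(2000)
        cfg = TEConfig(q=q)
        te = tsallis_entropy(x, cfg)
        assert 0.0 <= te <= cfg.max_te
        norm = tsallis_entropy(x, TEConfig(q=q, normalization="max_entropy"))
        assert 0.0 <= norm <= 1.0

    def test_q_one_and_bad_bins_rejected(self):
        with pytest.raises(ValueError, match="q"):
            TEConfig(q=1.0)
        with pytest.raises(ValueError, match="n_bins"):
            TEConfig(n_bins=1)

    def test_epoch_length_robustness(self):
        # 170 s vs 180 s of the same stationary signal: < 2 % difference
        rng = np.random.default_rng(11)
        x = rng.standard_normal(int(180 * FS))
        cfg = TEConfig()
        te_180 = tsallis_entropy(x, cfg)
        te_170 = tsallis_entropy(x[: int(170 * FS)], cfg)
        assert abs(te_170 - te_180) / te_180 < 0.02

    def test_spectral_ratio_estimator_available(self):
        rng = np.random.default_rng(5)
        cfg = TEConfig(estimator="spectral_ratio")
        broadband = rng.standard_normal(20_000)
        tone = np.sin(2 * np.pi * 7.0 * np.arange(20_000) / FS)
        # a pure tone concentrates spectral mass: far lower spectral TE
        assert tsallis_entropy(broadband, cfg) > tsallis_entropy(tone, cfg)


class TestRelativeBandPower:
    def test_pure_alpha_tone(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        frac = relative_band_power(x, CANONICAL_BANDS, FS)
        assert frac[2] >= 0.95  # alpha band

    def test_five_equal_tones_match_periodogram_oracle(self):
        t = np.arange(int(60 * FS)) / FS
        freqs = [2.5, 6.0, 10.0, 20.0, 37.0]
        x = sum(np.sin(2 * np.pi * f * t + 0.3 * i) for i, f in enumerate(freqs))
        frac = relative_band_power(x, CANONICAL_BANDS, FS)
        np.testing.assert_allclose(frac, 0.2, atol=0.02)
        # periodogram-integration oracle
        psd = np.abs(np.fft.rfft(x)) ** 2
        f = np.fft.rfftfreq(len(x), 1 / FS)
        p = np.array(
            [psd[(f >= b.lo) & (f < b.hi)].sum() for b in CANONICAL_BANDS]
        )
        np.testing.assert_allclose(frac, p / p.sum(), atol=0.02)

    def test_scale_invariance_and_sum_to_one(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(30 * FS))
        f1 = relative_band_power(x, CANONICAL_BANDS, FS)
        f2 = relative_band_power(10.0 * x, CANONICAL_BANDS, FS)
        np.testing.assert_allclose(f1, f2, atol=1e-9)
        assert f1.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            relative_band_power(np.zeros(int(30 * FS)), CANONICAL_BANDS, FS)


class TestFeatureTable:
    def test_toy_counts_and_global_median(self):
        rng = np.random.default_rng(9)
        names, roi_map = synthetic_montage(10)
        recs = []
        for sid in ("a", "b"):
            recs.append(
                EEGRecording(
                    subject_id=sid,
                    condition="EO",
                    data=rng.normal(size=(10, int(30 * FS))),
                    fs=FS,
                    channel_names=names,
                    roi_map=roi_map,
                )
            )
        table = compute_feature_table(
            recs, bands=[THETA], groups={"a": "PD", "b": "PD"}
        )
        assert len(table.electrodes) == 2 * 10  # subjects x electrodes x 1 band
        sub_a = table.electrodes[table.electrodes.subject == "a"]
        expected = float(np.median(sub_a["te"]))
        got = table.global_median("theta", "EO").loc["a"]
        assert got == pytest.approx(expected)

    def test_excluded_channels_skipped(self):
        rng = np.random.default_rng(10)
        names, roi_map = synthetic_montage(12, n_excluded=2)
        rec = EEGRecording(
            subject_id="a",
            condition="EC",
            data=rng.normal(size=(12, int(30 * FS))),
            fs=FS,
            channel_names=names,
            roi_map=roi_map,
        )
        table = compute_feature_table([rec], bands=[THETA])
        assert len(table.electrodes) == 10
        assert "excluded" not in set(table.electrodes["roi"])

    def test_failure_carries_subject_identity(self):
        names, roi_map = synthetic_montage(10)
        rec = EEGRecording(
            subject_id="bad",
            condition="EC",
            data=np.zeros((10, int(30 * FS))),
            fs=FS,
            channel_names=names,
            roi_map=roi_map,
        )
        with pytest.raises(RuntimeError, match="bad"):
            compute_feature_table([rec], bands=[THETA])
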