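"""Filtering, peak detection, FFT and spectrogram imaging against
independent oracles (analytic magnitude responses, brute-force scans,
naive DFT)."""
from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import butter, sosfreqz

import ecgstress as e


def sinusoid_record(freq, fs=360.0, duration=10.0, amplitude=1.0):
    t = np.arange(int(duration * fs)) / fs
    return e.ECGRecord(samples=amplitude * np.sin(2 * np.pi * freq * t), fs=fs)


def filtfilt_gain(freq, spec):
    """Analytic amplitude gain of the zero-phase filter at one frequency."""
    sos = butter(spec.order, spec.cutoff, btype="low", fs=spec.fs, output="sos")
    _, h = sosfreqz(sos, worN=[freq], fs=spec.fs)
    return float(np.abs(h[0]) ** 2)  # forward-backward squares the magnitude


def trimmed_rms(x, n=200):
    return float(np.sqrt(np.mean(x[n:-n] ** 2)))


class TestLowpass:
    def test_dc_gain_is_unity(self):
        rec = e.ECGRecord(samples=np.full(2000, 0.7), fs=360.0)
        out = e.apply_lowpass(rec)
        np.testing.assert_allclose(out.samples, rec.samples, atol=1e-6)

    def test_stopband_attenuation_matches_analytic_response(self):
        rec = sinusoid_record(170.0)
        out = e.apply_lowpass(rec)
        gain = trimmed_rms(out.samples) / trimmed_rms(rec.samples)
        assert gain < 0.5
        assert gain == pytest.approx(filtfilt_gain(170.0, e.FilterSpec()), rel=0.05)

    def test_passband_gain_near_unity(self):
        rec = sinusoid_record(10.0)
        out = e.apply_lowpass(rec)
        assert trimmed_rms(out.samples) == pytest.approx(trimmed_rms(rec.samples), rel=0.01)

    def test_zero_phase_preserves_peak_time(self):
        rec = e.synth_record(replace(e.WITHOUT_STRESS, duration=5.0, seed=1))
        before = e.detect_peaks(rec).r_indices
        after = e.detect_peaks(e.apply_lowpass(rec)).r_indices
        assert before.size == after.size
        assert np.max(np.abs(before - after)) <= 1

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            e.FilterSpec(fs=360.0, cutoff=180.0).validate()

    def test_fs_mismatch_rejected(self):
        rec = sinusoid_record(10.0, fs=700.0)
        with pytest.raises(ValueError, match="resample"):
            e.apply_lowpass(rec)

    def test_output_length_equals_input(self):
        rec = sinusoid_record(30.0, duration=3.0)
        assert e.apply_lowpass(rec).n_samples == rec.n_samples


class TestResample:
    def test_same_fs_identity(self):
        rec = sinusoid_record(10.0)
        out = e.resample(rec, rec.fs)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_halving_matches_closed_form_sinusoid(self):
        rec = sinusoid_record(10.0, fs=720.0, duration=4.0)
        out = e.resample(rec, 360.0)
        assert abs(out.n_samples - rec.n_samples / 2) <= 1
        t = np.arange(out.n_samples) / 360.0
        expected = np.sin(2 * np.pi * 10.0 * t)
        inner = slice(100, -100)
        err = np.max(np.abs(out.samples[inner] - expected[inner]))
        assert err < 0.01

    def test_duration_preserved(self):
        rec = sinusoid_record(5.0, fs=700.0, duration=3.0)
        out = e.resample(rec, 360.0)
        assert abs(out.duration - rec.duration) <= 1.0 / 360.0


class TestNoiseReduction:
    def test_no_reduction_is_zero(self):
        rec = sinusoid_record(170.0)
        assert e.noise_reduction_percent(rec, rec) == pytest.approx(0.0, abs=1e-9)

    def test_brickwall_is_100(self):
        rec = sinusoid_record(170.0, duration=10.0)
        spectrum = np.fft.rfft(rec.samples)
        freqs = np.fft.rfftfreq(rec.n_samples, 1 / rec.fs)
        spectrum[freqs > 150.0] = 0.0
        ideal = rec.copy_with(samples=np.fft.irfft(spectrum, rec.n_samples))
        assert e.noise_reduction_percent(rec, ideal) == pytest.approx(100.0, abs=1e-6)

    def test_matches_analytic_attenuation_of_stopband_tone(self):
        fs, duration = 360.0, 10.0
        t = np.arange(int(fs * duration)) / fs
        raw = e.ECGRecord(
            samples=np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 170 * t), fs=fs
        )
        filtered = e.apply_lowpass(raw)
        got = e.noise_reduction_percent(raw, filtered)
        gain = filtfilt_gain(170.0, e.FilterSpec())
        expected = 100.0 * (1.0 - gain**2)  # power gain is amplitude gain squared
        assert got == pytest.approx(expected, rel=0.02)

    def test_no_outofband_power_gives_nan(self):
        rec = sinusoid_record(10.0)
        assert np.isnan(e.noise_reduction_percent(rec, rec))


def brute_force_peaks(x, threshold, distance, kind):
    """Independent oracle: supra-threshold local extrema, greedy spacing
    enforcement keeping the greatest amplitude first."""
    s = x if kind == "max" else -x
    level = threshold if kind == "max" else -threshold
    candidates = [
        i for i in range(1, len(s) - 1)
        if s[i] > level and s[i] > s[i - 1] and s[i] >= s[i + 1]
    ]
    candidates.sort(key=lambda i: -s[i])
    kept: list[int] = []
    for i in candidates:
        if all(abs(i - j) >= distance for j in kept):
            kept.append(i)
    return sorted(kept)


class TestDetectPeaks:
    def test_single_r_peak(self):
        rec = e.ECGRecord(samples=np.array([0.0, 0.5, 0.0]), fs=2.0)
        feats = e.detect_peaks(rec)
        assert feats.r_indices.tolist() == [1]
        assert feats.s_indices.size == 0

    def test_single_s_peak(self):
        rec = e.ECGRecord(samples=np.array([0.0, -0.6, 0.0]), fs=2.0)
        feats = e.detect_peaks(rec)
        assert feats.s_indices.tolist() == [1]
        assert feats.r_indices.size == 0

    def test_counts_and_mean_span_on_clean_record(self):
        # 10 beats with R = +1.2 mV, S = −0.4 mV placed one per second
        tpl = e.BeatTemplate()
        tpl = replace(tpl, r=replace(tpl.r, amplitude=1.2), s=replace(tpl.s, amplitude=-0.4))
        fs = 360.0
        seg = e.synth_beat(tpl, fs)
        x = np.zeros(int(10 * fs))
        for k in range(10):
            start = int(k * fs)
            x[start : start + seg.size] += seg
        rec = e.ECGRecord(samples=x, fs=fs)
        thr = e.PeakThresholds(r_threshold=0.2, s_threshold=-0.2)
        feats = e.detect_peaks(rec, thr)
        assert feats.r_indices.size == 10
        assert feats.s_indices.size == 10
        assert np.mean(feats.rs_amplitudes) == pytest.approx(1.6, rel=0.01)

    def test_matches_brute_force_oracle(self):
        cfg = replace(e.UNDER_STRESS, duration=20.0, rr_jitter=0.03, rs_jitter=0.2, seed=13)
        rec = e.synth_record(cfg)
        thr = e.PeakThresholds()
        feats = e.detect_peaks(rec, thr)
        distance = int(round(thr.refractory * rec.fs))
        assert feats.r_indices.tolist() == brute_force_peaks(
            rec.samples, thr.r_threshold, distance, "max"
        )
        assert feats.s_indices.tolist() == brute_force_peaks(
            rec.samples, thr.s_threshold, distance, "min"
        )

    def test_rr_intervals_consistent(self):
        rec = e.synth_record(replace(e.WITHOUT_STRESS, duration=10.0, seed=3))
        feats = e.detect_peaks(rec)
        assert feats.rr_intervals.size == feats.r_indices.size - 1
        assert np.all(feats.rr_intervals > 0)
        assert np.all(np.diff(feats.r_indices) > 0)

    def test_record_shorter_than_refractory_rejected(self):
        rec = e.ECGRecord(samples=np.zeros(50), fs=360.0)
        with pytest.raises(ValueError, match="refractory"):
            e.detect_peaks(rec)

    def test_no_peaks_is_empty_not_error(self):
        rec = e.ECGRecord(samples=np.zeros(1000), fs=360.0)
        feats = e.detect_peaks(rec)
        assert feats.n_beats == 0 and np.isnan(e.summarize_rs(feats))


class TestSummaries:
    def test_single_pair(self):
        feats = e.BeatFeatures(
            r_indices=np.array([10]), s_indices=np.array([14]),
            rr_intervals=np.array([]), rs_amplitudes=np.array([1.47]), fs=360.0,
        )
        assert e.summarize_rs(feats) == pytest.approx(1.47)

    def test_constant_pairs(self):
        feats = e.BeatFeatures(
            r_indices=np.array([1, 2]), s_indices=np.array([]),
            rr_intervals=np.array([1.0]), rs_amplitudes=np.array([2.0, 2.0]), fs=360.0,
        )
        assert e.summarize_rs(feats) == 2.0

    def test_matches_direct_mean_on_random_record(self):
        cfg = replace(e.UNDER_STRESS, duration=35.0, rs_jitter=0.3, seed=21)
        feats = e.detect_peaks(e.synth_record(cfg))
        assert feats.rs_amplitudes.size >= 50
        assert e.summarize_rs(feats) == pytest.approx(float(np.mean(feats.rs_amplitudes)))


def naive_dft_magnitude(x):
    n = len(x)
    k = np.arange(n // 2 + 1)
    w = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    return np.abs(w @ x)


class TestFrequencyDomain:
    def test_constant_concentrates_at_dc(self):
        rec = e.ECGRecord(samples=np.full(64, 3.0), fs=360.0)
        mag = e.to_frequency_domain(rec)
        assert mag[0] == pytest.approx(64 * 3.0)
        assert np.all(mag[1:] < 1e-9)

    def test_sinusoid_peaks_at_its_bin(self):
        n, k = 256, 17
        x = np.sin(2 * np.pi * k * np.arange(n) / n)
        mag = e.to_frequency_domain(e.ECGRecord(samples=x, fs=360.0))
        assert mag.argmax() == k

    def test_output_length_one_sided(self):
        rec = e.ECGRecord(samples=np.arange(101, dtype=float), fs=360.0)
        assert e.to_frequency_domain(rec).size == 51

    @pytest.mark.parametrize("n", [8, 63, 256, 1024])
    def test_matches_naive_dft(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        got = e.to_frequency_domain(e.ECGRecord(samples=x, fs=360.0))
        expected = naive_dft_magnitude(x)
        np.testing.assert_allclose(got, expected, rtol=1e-8, atol=1e-8)


class TestSpectrogram:
    def test_zero_series_gives_zero_image(self):
        img = e.to_spectrogram(np.zeros(2000), e.STFTParams(image_size=32), fs=360.0)
        assert np.all(img.pixels == 0.0)

    def test_shape_and_range_contract(self):
        rng = np.random.default_rng(0)
        img = e.to_spectrogram(rng.normal(size=3000), e.STFTParams(image_size=124), fs=360.0)
        assert img.pixels.shape == (124, 124, 3)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
        assert np.all(np.isfinite(img.pixels))

    def test_deterministic(self):
        x = np.sin(np.arange(4000) * 0.05)
        a = e.to_spectrogram(x, e.STFTParams(image_size=48), fs=360.0)
        b = e.to_spectrogram(x, e.STFTParams(image_size=48), fs=360.0)
        assert np.array_equal(a.pixels, b.pixels)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            e.to_spectrogram(np.array([1.0]), e.STFTParams(), fs=360.0)


class TestBuildDataset:
    def test_doubling_and_labels(self, corpus, image_sets):
        records, _ = corpus
        time_imgs, freq_imgs = image_sets
        assert len(time_imgs) == len(records)
        assert len(freq_imgs) == len(records)
        for rec, ti, fi in zip(records, time_imgs, freq_imgs):
            assert ti.label == rec.label == fi.label
            assert ti.domain == "time" and fi.domain == "frequency"

    def test_single_record(self):
        rec = e.synth_record(replace(e.WITHOUT_STRESS, duration=6.0, seed=2))
        ti, fi = e.build_dataset([rec], stft_params=e.STFTParams(image_size=24))
        assert len(ti) == 1 and len(fi) == 1

    def test_resamples_foreign_rate(self):
        cfg = replace(e.WITHOUT_STRESS, fs=700.0, duration=6.0, seed=2)
        ti, fi = e.build_dataset([e.synth_record(cfg)], stft_params=e.STFTParams(image_size=24))
        assert len(ti) == 1 and len(fi) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            e.build_dataset([])
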