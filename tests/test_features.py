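"""Feature-extraction tests: windows, spectra, contour, segmentation,
entropy, CPP, and ground-truth recovery on rendered whoops."""

import dataclasses

import numpy as np
import pytest

from whoopsig.features import (
    FeatureConfig,
    FundamentalContour,
    cpp_stats,
    detect_subharmonics,
    energy_window,
    extract_features,
    extract_table,
    resample_audio,
    segment_cf,
    segment_upsweep,
    spectral_entropy_mean,
    spectrum_summary,
    trace_fundamental,
    FEATURE_NAMES,
)
from whoopsig.synth import (
    SynthWhoopParams,
    WhoopRecord,
    contour_frequency,
    render_whoop,
    truth_features,
)

FS = 32000.0


def tone(freq, dur=1.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def record(wave, fs=FS):
    return WhoopRecord(waveform=wave, sample_rate=fs, whoop_id="w", bout_id="b",
                       caller_id="h", clan_id="c", position_in_bout=0,
                       whoop_type="S", age_months=60, sex="f")


class TestResample:
    def test_tone_survives_downsampling(self):
        rec = resample_audio(record(tone(700)), 8000)
        spec = np.abs(np.fft.rfft(rec.waveform))
        freqs = np.fft.rfftfreq(len(rec.waveform), 1 / 8000)
        assert abs(freqs[np.argmax(spec)] - 700) <= 8000 / len(rec.waveform)

    def test_identity_resample_is_noop(self):
        rec = record(tone(500))
        out = resample_audio(rec, FS)
        np.testing.assert_array_equal(out.waveform, rec.waveform)

    def test_duration_preserved(self):
        out = resample_audio(record(tone(500, dur=1.0)), 8000)
        assert abs(len(out.waveform) - 8000) <= 1

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            resample_audio(record(tone(500)), 0)


class TestEnergyWindow:
    def test_rectangular_burst_recovered(self):
        x = np.zeros(40000)
        x[10000:30000] = tone(700, dur=20000 / FS)
        t0, t1 = energy_window(x, FS)
        assert t0 == pytest.approx(10000 / FS, abs=0.01 * (20000 / FS))
        assert t1 == pytest.approx(30000 / FS, abs=0.01 * (20000 / FS))

    def test_unit_impulse_gives_one_sample_window(self):
        x = np.zeros(1000)
        x[123] = 1.0
        t0, t1 = energy_window(x, FS)
        assert t0 == pytest.approx(123 / FS)
        assert (t1 - t0) == pytest.approx(1 / FS)

    def test_ramp_envelope_matches_cumulative_scan_oracle(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, 5000) * rng.standard_normal(5000)
        t0, t1 = energy_window(x, FS, fraction=0.99)
        # oracle: direct cumulative-energy scan
        cum = np.cumsum(x**2) / np.sum(x**2)
        i0 = next(i for i, v in enumerate(cum) if v >= 0.005)
        i1 = next(i for i, v in enumerate(cum) if v >= 0.995)
        assert t0 == pytest.approx(i0 / FS)
        assert t1 == pytest.approx((i1 + 1) / FS)

    def test_silent_input_rejected(self):
        with pytest.raises(ValueError, match="silent"):
            energy_window(np.zeros(100), FS)


class TestSpectrumSummary:
    def test_pure_tone(self):
        x = tone(800)
        peak, cen = spectrum_summary(x, FS, (0.0, 1.0))
        bin_khz = FS / len(x) / 1000
        assert peak == pytest.approx(0.8, abs=bin_khz)
        assert cen == pytest.approx(0.8, abs=0.01)

    def test_equal_tone_pair_centroid_is_midpoint(self):
        x = tone(600) + tone(1000)
        _, cen = spectrum_summary(x, FS, (0.0, 1.0))
        assert cen == pytest.approx(0.8, abs=0.01)

    def test_unequal_pair_matches_weighted_mean(self):
        # power ratio 1:3 at 600/1000 Hz -> centroid 0.25*600 + 0.75*1000
        x = tone(600, amp=1.0) + tone(1000, amp=np.sqrt(3.0))
        _, cen = spectrum_summary(x, FS, (0.0, 1.0))
        assert cen == pytest.approx(0.9, abs=0.01)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            spectrum_summary(tone(500), FS, (0.5, 0.5))


class TestTraceFundamental:
    def test_flat_tone_traces_flat(self):
        contour = trace_fundamental(tone(700, dur=2.0), FS)
        bin_hz = FS / FeatureConfig().trace_nfft
        assert np.all(np.abs(contour.freqs - 700) <= bin_hz)

    def test_whoop_contour_recovered_at_20db(self):
        p = SynthWhoopParams(whoop_type="A", f0_cf=750, f0_max=1000, dur=2.5,
                             cf_start=0.15, cf_end=1.2, upsweep_end=2.2, snr_db=20.0)
        rec = render_whoop(p, FS, rng=np.random.default_rng(1))
        contour = trace_fundamental(rec.waveform, FS)
        true = contour_frequency(p, contour.times)
        rel = np.abs(contour.freqs - true) / true
        assert np.median(rel) <= 0.02

    def test_anchor_contour_passes_through(self):
        anchor = FundamentalContour(times=np.array([0.2, 1.0, 1.8]),
                                    freqs=np.array([700.0, 750.0, 900.0]),
                                    frame_hop=0.008)
        out = trace_fundamental(tone(700, dur=2.0), FS, anchor=anchor)
        expected = np.interp(out.times, anchor.times, anchor.freqs)
        np.testing.assert_allclose(out.freqs, expected)

    def test_silence_has_no_voiced_frames(self):
        with pytest.raises(ValueError, match="voiced"):
            trace_fundamental(np.zeros(32000), FS)


def make_contour(freqs, hop=0.008):
    freqs = np.asarray(freqs, dtype=float)
    times = hop / 2 + hop * np.arange(len(freqs))
    return FundamentalContour(times=times, freqs=freqs, frame_hop=hop)


class TestSegmentCF:
    def test_flat_then_steep_rise(self):
        # the rise leaves the +/-10% band within one frame, so the CF run is
        # the 1.0 s plateau
        hop = 0.008
        n_flat = 125  # 1.0 s plateau at 700 Hz
        freqs = np.concatenate([np.full(n_flat, 700.0),
                                np.linspace(790, 1000, 8)])
        marks, dur_cf, fmean = segment_cf(make_contour(freqs, hop))
        assert dur_cf == pytest.approx(1.0, abs=2 * hop)
        assert fmean == pytest.approx(0.700, abs=0.002)

    def test_entirely_flat_contour_runs_to_peak(self):
        freqs = 700 + 2 * np.sin(np.linspace(0, 3, 80))
        marks, dur_cf, _ = segment_cf(make_contour(freqs))
        peak = np.argmax(freqs)
        assert dur_cf == pytest.approx((peak + 1) * 0.008, abs=0.008)

    def test_peak_at_first_frame_flags_undefined_cf(self):
        freqs = np.linspace(1000, 700, 50)
        marks, dur_cf, _ = segment_cf(make_contour(freqs))
        assert dur_cf == 0.0 and not marks.cf_defined

    def test_matches_exhaustive_run_enumeration(self):
        # oracle: enumerate every contiguous pre-peak run inside the band
        rng = np.random.default_rng(2)
        hop = 0.008
        for _ in range(1000):
            n = int(rng.integers(5, 70))
            steps = rng.normal(0, 0.04, n)
            freqs = 700 * np.exp(np.cumsum(steps))
            contour = make_contour(freqs, hop)
            marks, dur_cf, fmean = segment_cf(contour)
            peak = int(np.argmax(freqs))
            if peak == 0:
                assert dur_cf == 0.0
                continue
            m = np.median(freqs[:peak])
            ok = (freqs[:peak + 1] >= 0.9 * m) & (freqs[:peak + 1] <= 1.1 * m)
            best_len, best_start = 0, None
            for i in range(peak + 1):
                for j in range(i, peak + 1):
                    if ok[i:j + 1].all() and (j - i + 1) > best_len:
                        best_len, best_start = j - i + 1, i
            if best_start is None:
                assert dur_cf == 0.0
            else:
                assert dur_cf == pytest.approx(best_len * hop)
                assert fmean == pytest.approx(
                    np.mean(freqs[best_start:best_start + best_len]) / 1000)


class TestSegmentUpsweep:
    def test_plateau_to_peak_duration(self):
        # rise starts outside the +/-10% band so the upsweep is the whole ramp
        freqs = np.concatenate([np.full(125, 700.0), np.linspace(790, 1000, 50)])
        contour = make_contour(freqs)
        marks, _, _ = segment_cf(contour)
        dur_up, up_end = segment_upsweep(contour, marks)
        assert dur_up == pytest.approx(50 * 0.008, abs=3 * 0.008)

    def test_flat_call_has_zero_upsweep(self):
        freqs = np.full(60, 650.0)
        freqs[-1] = 650.5
        contour = make_contour(freqs)
        marks, _, _ = segment_cf(contour)
        dur_up, _ = segment_upsweep(contour, marks)
        assert dur_up <= 0.008

    def test_recovered_upsweep_matches_generator(self):
        p = SynthWhoopParams(whoop_type="A", f0_cf=750, f0_max=1000, dur=2.5,
                             cf_start=0.15, cf_end=1.2, upsweep_end=2.2)
        rec = render_whoop(p, FS)
        feats = extract_features(rec)
        truth = truth_features(p)
        hop = FeatureConfig().trace_hop / FS
        assert feats.dur_upsweep == pytest.approx(truth["dur_upsweep"], abs=2 * hop)


class TestSubharmonics:
    def test_pure_harmonic_stack_has_none(self):
        p = SynthWhoopParams(whoop_type="S", f0_cf=700, f0_max=900, dur=2.0,
                             cf_start=0.1, cf_end=0.6, upsweep_end=1.2)
        rec = render_whoop(p, FS)
        feats = extract_features(rec)
        assert feats.dur_subharm == 0.0
        assert feats.harmonic_ratio_total == pytest.approx(60.0)

    def test_declared_interval_detected_with_high_jaccard(self):
        p = SynthWhoopParams(whoop_type="A", f0_cf=750, f0_max=1000, dur=2.5,
                             cf_start=0.1, cf_end=1.6, upsweep_end=2.2,
                             subharmonic_start=1.0, subharmonic_end=1.5,
                             subharmonic_level_db=6.0)
        rec = render_whoop(p, FS)
        config = FeatureConfig()
        from whoopsig.features import _stft_power
        contour = trace_fundamental(rec.waveform, FS, config)
        marks, _, _ = segment_cf(contour)
        intervals, dur_sub, _, _ = detect_subharmonics(
            rec.waveform, FS, contour, marks, config)
        inter = sum(max(0.0, min(e, 1.5) - max(s, 1.0)) for s, e in intervals)
        union = 0.5 + dur_sub - inter
        assert inter / union >= 0.8


class TestSpectralEntropy:
    def test_white_noise_approaches_one(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(8000)
        h = spectral_entropy_mean(x, 8000, (0.0, 1.0))
        assert 0.95 <= h <= 1.0

    def test_pure_tone_approaches_zero(self):
        x = np.sin(2 * np.pi * 700 * np.arange(8000) / 8000)
        h = spectral_entropy_mean(x, 8000, (0.0, 1.0))
        assert 0.0 <= h <= 0.35

    def test_two_equal_aligned_tones_give_closed_form(self):
        # rectangular window, no smoothing, tones on exact bins: H = ln 2 / ln N
        config = dataclasses.replace(FeatureConfig(), entropy_window="rect",
                                     entropy_avg_halfwidth_s=0.0)
        fs, block = 8000, 32
        t = np.arange(8000) / fs
        x = np.sin(2 * np.pi * 750 * t) + np.sin(2 * np.pi * 1500 * t)
        h = spectral_entropy_mean(x, fs, (0.0, 1.0), config)
        n_bins = block // 2 + 1
        assert h == pytest.approx(np.log(2) / np.log(n_bins), abs=0.02)

    def test_bounded_for_arbitrary_signals(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = rng.standard_normal(4000) * np.exp(rng.normal(0, 2))
            h = spectral_entropy_mean(x, 8000, (0.0, 0.5))
            assert 0.0 <= h <= 1.0


class TestCPP:
    longblock = dataclasses.replace(FeatureConfig(), cpp_block_s=0.032,
                                    cpp_hop_s=0.004)

    def test_periodic_train_beats_noise_by_wide_margin(self):
        # 250 Hz period is resolvable once the analysis block spans several periods
        fs = 8000
        train = np.zeros(fs)
        train[::32] = 1.0
        noise = np.random.default_rng(5).standard_normal(fs)
        cpp_train, _ = cpp_stats(train, fs, (0.0, 1.0), self.longblock)
        cpp_noise, _ = cpp_stats(noise, fs, (0.0, 1.0), self.longblock)
        assert cpp_train - cpp_noise >= 5.0

    def test_stationary_signal_has_small_cpp_sd(self):
        fs = 8000
        t = np.arange(fs) / fs
        x = sum(np.sin(2 * np.pi * 250 * k * t) / k for k in range(1, 9))
        mean, sd = cpp_stats(x, fs, (0.0, 1.0), self.longblock)
        assert sd < 0.1 * mean

    def test_amplitude_scaling_cancels(self):
        fs = 8000
        t = np.arange(fs) / fs
        x = sum(np.sin(2 * np.pi * 700 * k * t) / k for k in range(1, 5))
        m1, _ = cpp_stats(x, fs, (0.0, 1.0))
        m2, _ = cpp_stats(10 * x, fs, (0.0, 1.0))
        assert m1 == pytest.approx(m2, rel=1e-6)

    def test_impossible_quefrency_range_rejected(self):
        config = dataclasses.replace(FeatureConfig(), cpp_f0_low=1100.0,
                                     cpp_f0_high=1200.0, cpp_pad_factor=1)
        with pytest.raises(ValueError, match="quefrency"):
            cpp_stats(tone(700, fs=8000), 8000, (0.0, 1.0), config)


class TestExtractFeatures:
    def noiseless_s_whoop(self):
        return SynthWhoopParams(whoop_type="S", f0_cf=720, f0_max=980, dur=2.4,
                                cf_start=0.14, cf_end=0.6, upsweep_end=1.3)

    def test_recovery_on_noiseless_whoop(self):
        p = self.noiseless_s_whoop()
        feats = extract_features(render_whoop(p, FS))
        truth = truth_features(p)
        assert not feats.failed
        assert feats.dur == pytest.approx(truth["dur"], rel=0.05)
        assert feats.freq_max == pytest.approx(truth["freq_max"], rel=0.02)
        assert feats.freq_mean_cf == pytest.approx(truth["freq_mean_cf"], rel=0.02)

    def test_flat_call_has_equal_cf_and_upsweep_endtimes(self):
        p = SynthWhoopParams(whoop_type="T", f0_cf=600, f0_max=603, dur=2.0,
                             cf_start=0.1, cf_end=1.9, upsweep_end=1.9)
        feats = extract_features(render_whoop(p, FS))
        assert feats.endtime_upsweep == pytest.approx(feats.endtime_cf, abs=0.05)

    def test_invariants_hold_across_types(self):
        rng = np.random.default_rng(6)
        from whoopsig.synth import PopulationSpec, BoutSpec, generate_bout, sample_population
        sig = sample_population(PopulationSpec(seed=13))[0]
        bout = generate_bout(sig, BoutSpec(length_min=6, length_max=6), rng, snr_db=25.0)
        for p in bout:
            feats = extract_features(render_whoop(p, FS, rng=rng))
            assert not feats.failed
            feats.validate()  # raises on any violated bound

    def test_scale_invariance_of_all_features(self):
        p = self.noiseless_s_whoop()
        rec = render_whoop(p, FS)
        big = dataclasses.replace(rec, waveform=10.0 * rec.waveform)
        f1, f2 = extract_features(rec), extract_features(big)
        for name in FEATURE_NAMES:
            assert getattr(f1, name) == pytest.approx(getattr(f2, name), rel=1e-5), name

    def test_batch_flags_failures_without_dropping_rows(self):
        p = self.noiseless_s_whoop()
        good = render_whoop(p, FS)
        bad = dataclasses.replace(good, waveform=np.zeros(1000), whoop_id="bad")
        table = extract_table([good, bad])
        assert len(table) == 2
        assert not table["failed"].iloc[0]
        assert table["failed"].iloc[1]
        assert "silent" in table["failure_reason"].iloc[1]
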