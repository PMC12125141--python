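"""Waveform-derived index estimators: HR, beats, BRS, PRx, trend averaging."""

import numpy as np
import pytest

from pshrisk import synthetic
from pshrisk.indices import (
    BeatSeries,
    compute_prx,
    detect_beats,
    estimate_brs_xcorr,
    estimate_hr_fft,
    trend_average,
    waveform_to_trend,
)
from pshrisk.io import UniformSeries


def series(values, dt=1 / 200, name="abp"):
    return UniformSeries(name, 0.0, dt, np.asarray(values, dtype=float), "mmHg")


class TestEstimateHr:
    def test_pure_tone_maps_to_bpm(self):
        t = np.arange(0, 60, 1 / 200)
        hr = estimate_hr_fft(series(80 + 10 * np.sin(2 * np.pi * 1.3 * t)))
        assert hr == pytest.approx(78.0, abs=1.0)

    def test_respiratory_tone_only_is_missing(self):
        t = np.arange(0, 60, 1 / 200)
        hr = estimate_hr_fft(series(80 + 5 * np.sin(2 * np.pi * 0.25 * t)))
        assert np.isnan(hr)

    def test_pulse_train_fundamental_wins_over_harmonics(self):
        t = np.arange(0, 60, 1 / 200)
        x = (np.sin(2 * np.pi * 1.0 * t)
             + 0.5 * np.sin(2 * np.pi * 2.0 * t)
             + 0.25 * np.sin(2 * np.pi * 3.0 * t))
        seg = series(80 + 10 * x)
        hr = estimate_hr_fft(seg)
        # independent check: dense spectrum of the same windowed signal
        w = np.hanning(t.size)
        spec = np.abs(np.fft.rfft((seg.values - seg.values.mean()) * w))
        freqs = np.fft.rfftfreq(t.size, 1 / 200)
        band = (freqs >= 0.67) & (freqs <= 2.33)
        expected = 60 * freqs[band][np.argmax(spec[band])]
        assert hr == pytest.approx(expected, abs=1e-9)
        assert hr == pytest.approx(60.0, abs=1.0)

    def test_short_segment_is_missing(self):
        t = np.arange(0, 10, 1 / 200)
        assert np.isnan(estimate_hr_fft(series(np.sin(2 * np.pi * t))))

    def test_invariant_to_offset_and_scale(self):
        t = np.arange(0, 60, 1 / 200)
        x = np.sin(2 * np.pi * 1.1 * t)
        a = estimate_hr_fft(series(80 + 10 * x))
        b = estimate_hr_fft(series(120 + 3 * x))
        assert a == b


class TestDetectBeats:
    def test_one_hz_pulse_yields_sixty_beats(self):
        wf = synthetic.gen_waveform(synthetic.WaveformParams(
            duration=60.5, pulse_freq=1.0, resp_amp=0, mayer_amp=0,
            slow_amp=0, brs_gain=0, noise_sd=0))
        beats = detect_beats(wf.abp)
        assert abs(len(beats) - 60) <= 1
        assert np.nanmean(beats.ibi) == pytest.approx(1000.0, rel=0.01)

    def test_constant_signal_yields_empty(self):
        beats = detect_beats(series(np.full(2000, 80.0)))
        assert len(beats) == 0

    def test_beat_count_matches_generator_ground_truth(self):
        wf = synthetic.gen_waveform(synthetic.WaveformParams(
            duration=120, brs_gain=6, noise_sd=0, seed=4))
        beats = detect_beats(wf.abp)
        assert abs(len(beats) - len(wf.ground_truth["beat_times"])) <= 1


class TestEstimateBrs:
    def test_constructed_unit_lag_relation_recovers_slope(self):
        # IBI[k] = 800 + 6*(SBP[k-1] - 120) with 1-s beat spacing
        rng = np.random.default_rng(3)
        n = 121
        t = np.arange(n, dtype=float)
        sbp = 120 + rng.normal(0, 5, n)
        ibi = np.full(n, np.nan)
        ibi[1:] = 800 + 6.0 * (sbp[:-1] - 120)
        beats = BeatSeries(t, sbp, ibi)
        est = estimate_brs_xcorr(beats)
        # oracle: direct least squares at the constructed lag
        slope = np.polyfit(sbp[:-1], ibi[1:], 1)[0]
        assert slope == pytest.approx(6.0, abs=1e-9)
        assert est == pytest.approx(6.0, rel=0.05)

    def test_constant_ibi_is_missing(self):
        t = np.arange(40, dtype=float)
        beats = BeatSeries(t, 120 + np.sin(t), np.full(40, 1000.0))
        assert np.isnan(estimate_brs_xcorr(beats))

    def test_gain_and_delay_recovered_from_generator(self):
        errs = []
        for seed in range(15):
            wf = synthetic.gen_waveform(synthetic.WaveformParams(
                duration=120, brs_gain=12.0, brs_delay=3.0, noise_sd=0.2,
                seed=seed))
            beats = detect_beats(wf.abp)
            errs.append(abs(estimate_brs_xcorr(beats) - 12.0) / 12.0)
        assert np.median(errs) < 0.10


class TestComputePrx:
    def mk_pair(self, coupling, seed=3):
        wf = synthetic.gen_waveform(synthetic.WaveformParams(
            duration=1800, pulse_amp=0, resp_amp=0, mayer_amp=0, brs_gain=0,
            slow_amp=2.0, icp_slow_coupling=coupling, noise_sd=0, seed=seed))
        return wf.abp, wf.icp

    @pytest.mark.parametrize("coupling", [1.0, -1.0])
    def test_perfect_coupling_saturates_prx(self, coupling):
        prx = compute_prx(*self.mk_pair(coupling))
        vals = prx.values[~np.isnan(prx.values)]
        assert vals.size > 0
        np.testing.assert_allclose(vals, coupling, atol=1e-9)

    def test_independent_channels_average_near_zero(self, rng):
        n = 5 * 3600  # 5 h at 1 Hz
        a = UniformSeries("abp", 0, 1.0, rng.normal(84, 3, n), "mmHg")
        c = UniformSeries("icp", 0, 1.0, rng.normal(11, 2, n), "mmHg")
        prx = compute_prx(a, c)
        assert abs(np.nanmean(prx.values)) < 0.1

    def test_affine_invariance_and_sign_flip(self, rng):
        n = 3600
        a = UniformSeries("abp", 0, 1.0, rng.normal(84, 3, n), "mmHg")
        c = UniformSeries("icp", 0, 1.0,
                          0.5 * a.values + rng.normal(0, 1, n), "mmHg")
        base = compute_prx(a, c).values
        scaled = compute_prx(
            UniformSeries("abp", 0, 1.0, 3 * a.values + 7, "mmHg"), c).values
        flipped = compute_prx(
            UniformSeries("abp", 0, 1.0, -2 * a.values, "mmHg"), c).values
        np.testing.assert_allclose(scaled, base, atol=1e-9)
        np.testing.assert_allclose(flipped, -base, atol=1e-9)

    def test_values_bounded(self, rng):
        a = UniformSeries("abp", 0, 1.0, rng.normal(84, 3, 3600), "mmHg")
        c = UniformSeries("icp", 0, 1.0, rng.normal(11, 2, 3600), "mmHg")
        vals = compute_prx(a, c).values
        vals = vals[~np.isnan(vals)]
        assert np.all((-1 <= vals) & (vals <= 1))


class TestTrendAverage:
    def test_constant_preserved(self):
        out = trend_average(series(np.full(12000, 7.0)))
        np.testing.assert_allclose(out.values, 7.0)

    def test_alternating_one_hz_means(self):
        x = np.tile([0.0, 2.0], 60)
        out = trend_average(UniformSeries("x", 0, 1.0, x))
        np.testing.assert_allclose(out.values, [1.0, 1.0])

    def test_bin_beyond_half_missing_is_missing(self):
        x = np.ones(120)
        x[:36] = np.nan  # 60% of first 60-sample bin at 1 Hz
        out = trend_average(UniformSeries("x", 0, 1.0, x))
        assert np.isnan(out.values[0]) and out.values[1] == 1.0


class TestWaveformToTrend:
    def test_derives_all_channels_on_trend_grid(self):
        wf = synthetic.gen_waveform(synthetic.WaveformParams(
            duration=600, pulse_freq=1.3, brs_gain=6, brs_delay=1,
            icp_slow_coupling=0.8, noise_sd=0.1, seed=8))
        rec = waveform_to_trend(wf)
        assert rec.n_samples == 10 and rec.dt == 60.0
        assert np.nanmean(rec.channels["hr"].values) == pytest.approx(78, abs=3)
        assert np.nanmean(rec.channels["abp"].values) == pytest.approx(84, abs=2)
        assert np.nanmean(rec.channels["brs"].values) == pytest.approx(6, rel=0.3)
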