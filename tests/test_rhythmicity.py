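import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhythmkit import synthetic as syn
from rhythmkit.rhythmicity import (autocorrelation, classify_cohort, classify_track,
                                   fit_damped_cosine, phase_to_ct, power_spectrum,
                                   raster_matrix)
from rhythmkit.traces import TimeSeriesTrace


def sine_trace(period, duration=120.0, dt=0.5, amp=1.0, mean=0.0):
    t = np.arange(0, duration, dt)
    return TimeSeriesTrace(t, mean + amp * np.sin(2 * np.pi * t / period))


class TestPowerSpectrum:
    def test_pure_sinusoid_period(self):
        psd = power_spectrum(sine_trace(24.0))
        assert psd.dominant_period == pytest.approx(24.0, abs=0.5)

    def test_two_tone_dominant_is_stronger(self):
        t = np.arange(0, 120, 0.5)
        v = np.sin(2 * np.pi * t / 24) + 0.3 * np.sin(2 * np.pi * t / 8)
        psd = power_spectrum(TimeSeriesTrace(t, v))
        # independent check: exhaustive DFT peak scan
        freqs = np.fft.rfftfreq(t.size, 0.5)
        mags = np.abs(np.fft.rfft(v))
        brute = 1.0 / freqs[1:][np.argmax(mags[1:])]
        assert psd.dominant_period == pytest.approx(24.0, abs=0.5)
        assert brute == pytest.approx(24.0, abs=1.0)

    def test_white_noise_dominant_periods_spread(self):
        # under the null the dominant frequency should not pile up in one bin
        hits_low = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            tr = TimeSeriesTrace(np.arange(0, 60, 0.5), rng.normal(size=120))
            psd = power_spectrum(tr, pad_factor=1)
            if psd.dominant_period > 20:
                hits_low += 1
        # only ~3/119 of the frequency bins lie above 20 h; allow 3x expectation
        assert hits_low <= 9

    def test_non_uniform_rejected(self):
        tr = TimeSeriesTrace([0, 1, 3, 7.0], [1, 2, 1, 2.0])
        with pytest.raises(ValueError):
            power_spectrum(tr)


class TestAutocorrelation:
    def test_sinusoid_signs_at_12_and_24(self):
        acf = autocorrelation(sine_trace(24.0), [12.0, 24.0])
        assert acf[0] < 0 and acf[1] > 0

    def test_lag_zero_is_one(self):
        assert autocorrelation(sine_trace(24.0), [0.0])[0] == pytest.approx(1.0)

    def test_white_noise_within_bartlett_bound(self):
        rng = np.random.default_rng(12)
        n = 2000
        tr = TimeSeriesTrace(np.arange(n) * 0.5, rng.normal(size=n))
        lags = np.arange(1, 101) * 0.5
        acf = autocorrelation(tr, lags)
        assert np.mean(np.abs(acf) <= 3 / np.sqrt(n)) >= 0.99

    def test_lag_beyond_record_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(sine_trace(24.0, duration=48.0), [60.0])


class TestClassification:
    @pytest.mark.parametrize("period,label", [(24.0, "circadian"), (8.0, "ultradian"),
                                              (15.0, "circadian"), (30.0, "circadian")])
    def test_single_track_labels(self, period, label):
        assert classify_track(sine_trace(period, mean=100.0)).label == label

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="short"):
            classify_track(sine_trace(24.0, duration=40.0))

    def test_affine_invariance(self):
        tr = sine_trace(22.0, mean=100.0)
        scaled = TimeSeriesTrace(tr.times, 7.5 * tr.values + 300.0)
        a, b = classify_track(tr), classify_track(scaled)
        assert a.label == b.label
        assert a.dominant_period == pytest.approx(b.dominant_period)

    def test_cohort_truth_agreement(self):
        traces, truth = syn.gen_cell_cohort(45, 10, 45,
                                            cfg=syn.SimConfig(seed=7, noise_sd=0.01))
        counts, calls = classify_cohort(traces)
        assert sum(counts.values()) == 100
        agreement = np.mean([c.label == t["label"] for c, t in zip(calls, truth)])
        assert agreement >= 0.90

    def test_single_circadian_cohort(self):
        traces, _ = syn.gen_cell_cohort(1, 0, 0, cfg=syn.SimConfig(seed=1, noise_sd=0.0))
        counts, _ = classify_cohort(traces)
        assert counts == {"circadian": 1, "ultradian": 0, "arrhythmic": 0}


class TestDampedCosineFit:
    def test_noiseless_roundtrip(self):
        cfg = syn.SimConfig(seed=0, noise_sd=0.0, duration=120.0, sampling_interval=0.5)
        tr = syn.gen_oscillatory_trace(100.0, 0.05, 24.7, phase=5.0,
                                       damping_rate=0.01, cfg=cfg)
        fit = fit_damped_cosine(tr)
        assert fit.period == pytest.approx(24.7, rel=1e-4)
        assert fit.amplitude == pytest.approx(5.0, rel=1e-4)
        assert fit.phase == pytest.approx(5.0, rel=1e-3)
        assert fit.damping == pytest.approx(0.01, rel=1e-3)
        assert fit.mesor == pytest.approx(100.0, rel=1e-6)
        # zero-residual limit: RSS << signal energy, RAE -> 0
        assert fit.rss < 1e-12 * np.sum((tr.values - tr.values.mean()) ** 2)
        assert fit.rae < 1e-6

    def test_cartilage_like_period_recovered(self):
        cfg = syn.SimConfig(seed=13, noise_sd=0.005, duration=120.0)
        tr = syn.gen_oscillatory_trace(100.0, 0.0664, 25.64, phase=9.4,
                                       damping_rate=0.005, cfg=cfg)
        fit = fit_damped_cosine(tr)
        assert fit.period == pytest.approx(25.64, abs=0.59)


class TestPhaseToCT:
    def test_zero_delta_is_ct12(self):
        assert phase_to_ct(10.0, 10.0, 24.0) == pytest.approx(12.0)

    def test_antiphase_is_ct0(self):
        assert phase_to_ct(22.0, 10.0, 24.0) % 24.0 == pytest.approx(0.0)

    def test_scn_peak_mapping(self):
        # fluorescence peak 7.9 h after the luciferase peak maps to CT19.9
        assert phase_to_ct(17.9, 10.0, 24.0) == pytest.approx(19.9)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 100), st.floats(0, 100), st.floats(1, 48))
    def test_periodicity_in_delta(self, pv, pp, period):
        a = phase_to_ct(pv, pp, period)
        b = phase_to_ct(pv + period, pp, period)
        assert a == pytest.approx(b, abs=1e-6)


class TestRaster:
    def test_single_cell_row_normalized(self):
        mat, order = raster_matrix([sine_trace(24.0, mean=50.0)], sort_by="none")
        assert mat.shape[0] == 1
        assert mat.min() == pytest.approx(0.0) and mat.max() == pytest.approx(1.0)

    def test_phase_sorted_rows_monotone(self):
        cfg = syn.SimConfig(seed=21, noise_sd=0.0, duration=96.0)
        phases = [3.0, 15.0, 9.0, 21.0, 6.0]
        traces = [syn.gen_oscillatory_trace(100, 0.05, 24.0, phase=p, cfg=cfg)
                  for p in phases]
        _, order = raster_matrix(traces)
        assert np.array_equal(np.asarray(phases)[order], np.sort(phases))

    def test_column_mean_keeps_cohort_period(self):
        cfg = syn.SimConfig(seed=22, noise_sd=0.01, duration=96.0)
        traces = [syn.gen_oscillatory_trace(100, 0.05, 24.0, phase=2.0, cfg=cfg,
                                            rng=np.random.default_rng(i))
                  for i in range(10)]
        mat, _ = raster_matrix(traces, sort_by="none")
        mean_tr = TimeSeriesTrace(traces[0].times, mat.mean(axis=0))
        psd = power_spectrum(mean_tr.with_values(mean_tr.values - mean_tr.values.mean()))
        assert psd.dominant_period == pytest.approx(24.0, abs=1.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            raster_matrix([sine_trace(24.0, duration=48), sine_trace(24.0, duration=96)])
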