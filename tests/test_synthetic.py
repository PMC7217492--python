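import numpy as np
import pytest

from rhythmkit import synthetic as syn
from rhythmkit.decay import fit_one_phase_decay
from rhythmkit.fcs import BeamGeometry, fcs_model, fit_fcs
from rhythmkit.rhythmicity import power_spectrum


class TestSimConfig:
    def test_invalid_sampling_rejected(self):
        with pytest.raises(ValueError):
            syn.SimConfig(sampling_interval=0)

    def test_duration_must_cover_two_samples(self):
        with pytest.raises(ValueError):
            syn.SimConfig(sampling_interval=1.0, duration=1.5)

    def test_fixed_seed_bit_identical(self):
        cfg = syn.SimConfig(seed=42, noise_sd=0.02)
        a = syn.gen_oscillatory_trace(100, 0.05, 24, cfg=cfg)
        b = syn.gen_oscillatory_trace(100, 0.05, 24, cfg=cfg)
        assert a.values.tobytes() == b.values.tobytes()


class TestOscillatoryTrace:
    def test_noiseless_peak_matches_amplitude(self):
        cfg = syn.SimConfig(seed=0, noise_sd=0.0, duration=48.0, sampling_interval=0.5)
        tr = syn.gen_oscillatory_trace(100, 0.046, 24, phase=12.0, cfg=cfg)
        # at t = phase the cosine is 1: value = baseline * 1.046
        assert np.isclose(np.max(tr.values) - 100.0, 4.6, atol=1e-9)

    def test_zero_amplitude_constant(self):
        cfg = syn.SimConfig(noise_sd=0.0)
        tr = syn.gen_oscillatory_trace(100, 0.0, 24, cfg=cfg)
        assert np.allclose(tr.values, 100.0)

    def test_noise_variance_matches_model(self):
        # sample variance of residuals vs the noiseless model approximates
        # (noise_sd*baseline)^2, cross-checked against an independent draw
        cfg_n = syn.SimConfig(seed=1, noise_sd=0.01, duration=400.0)
        cfg_0 = syn.SimConfig(seed=1, noise_sd=0.0, duration=400.0)
        noisy = syn.gen_oscillatory_trace(100, 0.05, 24, cfg=cfg_n)
        clean = syn.gen_oscillatory_trace(100, 0.05, 24, cfg=cfg_0)
        resid_var = np.var(noisy.values - clean.values)
        indep = np.random.default_rng(999).normal(0, 0.01 * 100, size=len(noisy))
        assert resid_var == pytest.approx((0.01 * 100) ** 2, rel=0.15)
        assert resid_var == pytest.approx(np.var(indep), rel=0.2)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_oscillatory_trace(100, 0.05, -24)


class TestCohort:
    def test_counts_and_truth_proportions(self):
        traces, truth = syn.gen_cell_cohort(45, 10, 45, cfg=syn.SimConfig(seed=2))
        assert len(traces) == 100 and len(truth) == 100
        labels = [t["label"] for t in truth]
        assert labels.count("circadian") == 45
        assert labels.count("ultradian") == 10
        assert labels.count("arrhythmic") == 45

    def test_single_pure_trace(self):
        traces, truth = syn.gen_cell_cohort(1, 0, 0, cfg=syn.SimConfig(seed=3, noise_sd=0.0))
        tr, info = traces[0], truth[0]
        t = tr.times
        expect = 100.0 * (1 + 0.05 * np.cos(2 * np.pi * (t - info["phase_h"]) / info["period_h"]))
        assert np.allclose(tr.values, expect, rtol=1e-9)

    def test_arrhythmic_only_dominant_periods_long_or_absent(self):
        # exhaustive periodogram peak scan on each detrended random walk
        traces, _ = syn.gen_cell_cohort(0, 0, 30, cfg=syn.SimConfig(seed=4))
        long_dom = 0
        for tr in traces:
            coef = np.polyfit(tr.times, tr.values, 1)
            detr = tr.with_values(tr.values - np.polyval(coef, tr.times))
            psd = power_spectrum(detr)
            if psd.dominant_period > 30:
                long_dom += 1
        assert long_dom >= 27  # no systematic periodic component in 0-30 h

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_cell_cohort(0, 0, 0)


class TestDecayCourse:
    def test_half_life_identity(self):
        cfg = syn.SimConfig(noise_sd=0.0, sampling_interval=0.5, duration=4.0)
        tr = syn.gen_decay_course(1.0, 0.0, np.log(2), cfg=cfg)
        i = np.argmin(np.abs(tr.times - 1.0))
        assert np.isclose(tr.values[i], 0.5, atol=1e-12)

    def test_initial_value(self):
        cfg = syn.SimConfig(noise_sd=0.0, sampling_interval=0.1, duration=20.0)
        tr = syn.gen_decay_course(1.0, 0.1, 0.0866, cfg=cfg)
        assert tr.values[0] == pytest.approx(1.0)

    def test_noiseless_roundtrip_recovers_k(self):
        cfg = syn.SimConfig(noise_sd=0.0, sampling_interval=0.1, duration=20.0)
        tr = syn.gen_decay_course(1.0, 0.1, 0.0866, cfg=cfg)
        fit = fit_one_phase_decay(tr)
        assert fit.k == pytest.approx(0.0866, abs=1e-6)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_decay_course(1.0, 0.0, -1.0)


class TestFrapCurve:
    def test_fully_immobile_flat_at_floor(self):
        cfg = syn.SimConfig(noise_sd=0.0, sampling_interval=0.5, duration=60.0)
        cur = syn.gen_frap_curve(0.4, 0.0, 0.0, 0.1, 0.01, cfg=cfg)
        assert np.allclose(cur.raw[cur.times >= 0], 0.4)

    def test_closed_form_value(self):
        cfg = syn.SimConfig(noise_sd=0.0, sampling_interval=0.5, duration=300.0)
        cur = syn.gen_frap_curve(0.5, 0.10, 0.0, 0.1733, 0.01, cfg=cfg)
        i = np.argmin(np.abs(cur.times - 4.0))
        assert np.isclose(cur.raw[i], 0.55, atol=1e-3)

    def test_prebleach_frames(self):
        cur = syn.gen_frap_curve(0.5, 0.1, 0.1, 0.2, 0.02)
        assert cur.n_prebleach == 10
        assert np.all(cur.times[:10] < 0)
        assert np.allclose(cur.raw[:10], 1.0)

    def test_amplitude_budget_enforced(self):
        with pytest.raises(ValueError):
            syn.gen_frap_curve(0.5, 0.3, 0.3, 0.1, 0.01)


class TestFcsCurve:
    def test_amplitude_limit(self):
        beam = BeamGeometry()
        cur = syn.gen_fcs_curve(5.0, 1e-3, T=0.0, beam=beam,
                                lags=np.geomspace(1e-9, 1e-7, 10))
        assert cur.G[0] - 1 == pytest.approx(1 / 5.0, rel=1e-4)

    def test_decorrelation_limit(self):
        cur = syn.gen_fcs_curve(5.0, 1e-3, T=0.0, lags=np.geomspace(1.0, 100.0, 10))
        assert np.all(np.abs(cur.G - 1) < 1e-2 / 5.0)

    def test_noiseless_roundtrip(self):
        beam = BeamGeometry()
        cur = syn.gen_fcs_curve(2.0, 5e-3, T=0.1, tauT=5e-6, beam=beam,
                                cfg=syn.SimConfig(noise_sd=0.0))
        fit = fit_fcs(cur, beam)
        assert fit.N == pytest.approx(2.0, rel=1e-6)
        assert fit.tauD == pytest.approx(5e-3, rel=1e-6)

    def test_invalid_triplet_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_fcs_curve(2.0, 5e-3, T=1.2)


class TestActivityRecord:
    def test_repeat_template_day_correlation_one(self):
        rec = syn.gen_activity_record("repeat_template", bin_minutes=60, days=10,
                                      cfg=syn.SimConfig(seed=6))
        days = rec.counts.reshape(10, 24)
        for d in days[1:]:
            assert np.corrcoef(days[0], d)[0, 1] == pytest.approx(1.0)

    def test_noise_hourly_means_converge(self):
        short = syn.gen_activity_record("noise", bin_minutes=60, days=5,
                                        cfg=syn.SimConfig(seed=7))
        long = syn.gen_activity_record("noise", bin_minutes=60, days=400,
                                       cfg=syn.SimConfig(seed=7))

        def spread(rec, days):
            hourly = rec.counts.reshape(days, 24).mean(axis=0)
            return np.max(np.abs(hourly - rec.counts.mean()))

        assert spread(long, 400) < spread(short, 5)

    def test_six_minute_binning(self):
        rec = syn.gen_activity_record("sine", bin_minutes=6, days=10,
                                      cfg=syn.SimConfig(seed=8))
        assert rec.bins_per_day == 240

    def test_uneven_bin_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_activity_record("sine", bin_minutes=7, days=10)


class TestLambdaStackAndMask:
    def test_single_fluorophore_stack_is_spectrum(self):
        from rhythmkit.coloc import SpectraMatrix
        sp = SpectraMatrix(np.arange(5), np.array([[1, 2, 3, 2, 1.0]]))
        maps = np.ones((1, 4, 4))
        stack, truth = syn.gen_lambda_stack(sp, maps, cfg=syn.SimConfig(noise_sd=0.0))
        assert np.allclose(stack, sp.spectra[0])

    def test_sphere_volume_close_to_analytic(self):
        r = 3.287
        target = 4 / 3 * np.pi * r ** 3  # 148.9 fL
        mask, truth = syn.gen_nuclear_mask(target, voxel_dims=(0.2, 0.2, 0.5))
        assert truth["volume_fl"] == pytest.approx(target, abs=0.2 * 0.2 * 0.5)
        assert truth["volume_fl"] == pytest.approx(148.9, rel=0.01)

    def test_one_voxel_mask(self):
        mask, truth = syn.gen_nuclear_mask(0.02, voxel_dims=(0.2, 0.2, 0.5))
        assert mask.sum() == 1

    @pytest.mark.parametrize("target", [306.0, 147.0])
    def test_study_volume_fixtures(self, target):
        mask, truth = syn.gen_nuclear_mask(target)
        assert truth["volume_fl"] == pytest.approx(target, abs=0.02)

    def test_voxel_larger_than_volume_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_nuclear_mask(0.001, voxel_dims=(0.2, 0.2, 0.5))
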