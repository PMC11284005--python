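"""Cohort generator: bookkeeping, determinism, RR process, waveform."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from vtscreen.synthetic import (
    CohortSpec,
    ParamDist,
    default_param_dists,
    generate_rr_series,
    inject_vt_runs,
    sample_cohort,
    synthesize_ecg,
)

from conftest import make_profile


class TestSampleCohort:
    def test_counts_and_labels(self):
        profiles = sample_cohort(CohortSpec(n_c0=2, n_c1=1, seed=7))
        assert len(profiles) == 3
        assert [p.class_label for p in profiles] == ["C0", "C0", "C1"]

    def test_deterministic(self):
        spec = CohortSpec(n_c0=5, n_c1=5, seed=42)
        a = sample_cohort(spec)
        b = sample_cohort(spec)
        assert all(pa.__dict__ == pb.__dict__ for pa, pb in zip(a, b))

    def test_zero_effect_scale_gives_identical_distributions(self):
        spec = CohortSpec(n_c0=500, n_c1=500, effect_size_scale=0.0, seed=11)
        profiles = sample_cohort(spec)
        x = [p.pvc_prob for p in profiles if p.class_label == "C0"]
        y = [p.pvc_prob for p in profiles if p.class_label == "C1"]
        assert ks_2samp(x, y).pvalue > 0.01

    def test_negative_sd_rejected(self):
        params = default_param_dists()
        params["rr_sd"] = ParamDist(40.0, -1.0)
        with pytest.raises(ValueError, match="standard deviation"):
            sample_cohort(CohortSpec(n_c0=1, n_c1=0, params=params, seed=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sample_cohort(CohortSpec(n_c0=-1, n_c1=1, seed=0))


class TestRrSeries:
    def test_no_pvc_means_all_normal(self):
        gt = generate_rr_series(make_profile(pvc_prob=0.0), 0.2, seed=1)
        assert set(gt.beat_labels) == {"N"}

    def test_degenerate_process_is_constant(self):
        profile = make_profile(mean_hr=60.0, rr_sd=0.0, lf_amp=0.0, hf_amp=0.0)
        gt = generate_rr_series(profile, 0.2, seed=1)
        assert np.allclose(gt.rr_series, 1000.0)

    def test_pvc_fraction_in_binomial_interval(self):
        # ~7200 beats at HR 70 over 1.7 h; central 99% interval for p=0.05
        profile = make_profile(pvc_prob=0.05, mean_hr=70.0)
        gt = generate_rr_series(profile, 1.7, seed=3)
        n = len(gt.beat_labels)
        assert n > 6000
        sd = np.sqrt(0.05 * 0.95 / n)
        assert 0.05 - 2.58 * sd < gt.realized_pvc_fraction < 0.05 + 2.58 * sd

    def test_pvc_prevalence_recovery_large_n(self):
        profile = make_profile(pvc_prob=0.05, mean_hr=75.0)
        gt = generate_rr_series(profile, 12.0, seed=9)
        assert len(gt.beat_labels) >= 50_000
        assert abs(gt.realized_pvc_fraction - 0.05) < 0.005

    def test_duration_conservation(self):
        profile = make_profile(mean_hr=75.0)
        gt = generate_rr_series(profile, 1.0, seed=3)
        assert 3600.0 - profile.mean_rr_ms / 1000.0 <= np.sum(gt.rr_series) / 1000.0 <= 3600.0

    def test_rr_clipped_to_physiologic_range(self):
        gt = generate_rr_series(make_profile(rr_sd=120.0, pvc_prob=0.2), 0.5, seed=5)
        assert gt.rr_series.min() >= 300.0 and gt.rr_series.max() <= 2500.0

    def test_compensatory_pause_arithmetic(self):
        # coupling 0.6 at constant RR 1000: V interval ~600, next ~1400
        profile = make_profile(mean_hr=60.0, rr_sd=0.0, lf_amp=0.0, hf_amp=0.0,
                               pvc_prob=0.05, pvc_coupling=0.6)
        gt = generate_rr_series(profile, 0.5, seed=2)
        v = np.flatnonzero(gt.beat_labels == "V")
        v = v[(v > 6) & (v < len(gt.rr_series) - 1)]
        # isolated PVCs only: the local mean RR window must be PVC-free
        v = np.array([i for i in v if not np.any(gt.beat_labels[i - 6:i] == "V")])
        assert len(v) > 5
        assert np.allclose(gt.rr_series[v], 600.0, atol=1.0)
        assert np.allclose(gt.rr_series[v + 1], 1400.0, atol=1.0)

    def test_deterministic(self):
        a = generate_rr_series(make_profile(pvc_prob=0.02), 0.3, seed=4)
        b = generate_rr_series(make_profile(pvc_prob=0.02), 0.3, seed=4)
        assert np.array_equal(a.rr_series, b.rr_series)
        assert np.array_equal(a.beat_labels, b.beat_labels)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_rr_series(make_profile(), 0.0, seed=1)


class TestSynthesizeEcg:
    def test_signal_length(self):
        gt = generate_rr_series(make_profile(), 0.5, seed=1)
        rec, _ = synthesize_ecg(gt, make_profile(), 250.0, seed=2)
        assert rec.n_samples == 450_000
        assert rec.n_leads == 3

    def test_r_peak_is_local_maximum(self):
        # noiseless: argmax within +/-50 ms of each annotated R time
        profile = make_profile(noise_level=0.0, hf_amp=0.0, lf_amp=0.0)
        gt = generate_rr_series(profile, 0.05, seed=1)
        rec, anns = synthesize_ecg(gt, profile, 250.0, seed=2)
        sig = rec.signal[0]
        w = int(0.05 * 250)
        for a in anns[1:-1]:
            lo = a.r_sample - w
            peak = lo + np.argmax(sig[lo:a.r_sample + w + 1])
            assert abs(peak - a.r_sample) <= 2

    def test_v_beat_rendered_wide(self):
        # single V complex spans > 120 ms above 10% of its amplitude
        from vtscreen.synthetic import GroundTruth
        profile = make_profile(noise_level=0.0, pvc_width_factor=2.0)
        gt = GroundTruth(rr_series=np.array([1000.0]), beat_times=np.array([2.0]),
                         beat_labels=np.array(["V"]), duration_s=4.0)
        rec, _ = synthesize_ecg(gt, profile, 250.0, seed=0)
        sig = np.abs(rec.signal[0])
        qrs = sig[int(1.7 * 250):int(2.25 * 250)]  # QRS region, T excluded
        span = np.flatnonzero(qrs > 0.1 * qrs.max())
        assert (span[-1] - span[0]) / 250.0 * 1000.0 > 120.0

    def test_low_fs_rejected(self):
        gt = generate_rr_series(make_profile(), 0.05, seed=1)
        with pytest.raises(ValueError, match="fs"):
            synthesize_ecg(gt, make_profile(), 50.0)

    def test_lead_gains_scale_clean_content(self):
        profile = make_profile(noise_level=0.005)
        gt = generate_rr_series(profile, 0.05, seed=1)
        rec, _ = synthesize_ecg(gt, profile, 250.0, seed=2)
        # lead 0 has unit gain, lead 1 is attenuated
        assert np.percentile(np.abs(rec.signal[0]), 99.9) > \
            np.percentile(np.abs(rec.signal[1]), 99.9)


class TestInjectVtRuns:
    def test_zero_runs_is_identity(self):
        profile = make_profile(pvc_prob=0.01)
        gt = generate_rr_series(profile, 0.5, seed=1)
        _, gt2 = inject_vt_runs(gt, profile, 128.0, n_runs=0, seed=3)
        assert np.array_equal(gt.rr_series, gt2.rr_series)
        assert gt2.vt_runs == []

    def test_run_geometry(self):
        profile = make_profile()
        gt = generate_rr_series(profile, 0.5, seed=1)
        _, gt2 = inject_vt_runs(gt, profile, 128.0, n_runs=1,
                                run_length_beats=3, run_rate_bpm=150.0, seed=3)
        assert len(gt2.vt_runs) == 1
        v = np.flatnonzero(gt2.beat_labels == "V")
        runs = np.split(v, np.flatnonzero(np.diff(v) > 1) + 1)
        run = max(runs, key=len)
        assert len(run) == 3
        assert np.allclose(gt2.rr_series[run], 400.0)

    def test_window_overlap_matches_brute_force(self):
        from vtscreen.preprocess import split_windows
        profile = make_profile(pvc_prob=0.01, noise_level=0.02)
        fs = 128.0
        gt = generate_rr_series(profile, 2.0, seed=1)
        rec, gt2 = inject_vt_runs(gt, profile, fs, n_runs=2,
                                  run_length_beats=5, run_rate_bpm=150.0, seed=4)
        windows = split_windows(rec, 30.0)
        wlen = int(30 * 60 * fs)
        brute = [any(a < (k + 1) * wlen and b > k * wlen for a, b in gt2.vt_runs)
                 for k in range(len(windows))]
        assert [w.contains_vt for w in windows] == brute
        assert sum(brute) >= 1

    def test_invalid_parameters_rejected(self):
        profile = make_profile()
        gt = generate_rr_series(profile, 0.2, seed=1)
        with pytest.raises(ValueError):
            inject_vt_runs(gt, profile, 128.0, n_runs=1, run_length_beats=2)
        with pytest.raises(ValueError):
            inject_vt_runs(gt, profile, 128.0, n_runs=1, run_rate_bpm=90.0)
        with pytest.raises(ValueError, match="length"):
            inject_vt_runs(gt, profile, 128.0, n_runs=100, run_length_beats=100)
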