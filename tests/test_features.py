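"""HRV and morphological feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vtscreen.beats import BeatAnnotation
from vtscreen.features import (
    HRV_FEATURES,
    MOR_FEATURES,
    PI_FEATURES,
    RRSeries,
    assemble_features,
    compute_rr,
    dfa_slope,
    hrv_fragmentation,
    hrv_frequency,
    hrv_nonlinear,
    hrv_time,
    mor_features,
    sample_entropy,
)


def rrs(nn, labels=None):
    nn = np.asarray(nn, dtype=float)
    t = np.cumsum(nn) / 1000.0
    labels = np.asarray(labels) if labels is not None else np.full(len(nn), "N")
    return RRSeries(times_s=t, intervals_ms=nn, labels=labels)


rr_series_strategy = st.lists(
    st.floats(min_value=400.0, max_value=1800.0), min_size=30, max_size=200
).map(rrs)


class TestComputeRr:
    def test_uniform_beats(self):
        anns = [BeatAnnotation(r_sample=s) for s in (0, 1000, 2000, 3000)]
        rr = compute_rr(anns, fs=1000.0)
        assert np.allclose(rr.intervals_ms, 1000.0)
        assert rr.valid_mask.all()

    def test_long_gap_marked_invalid(self):
        anns = [BeatAnnotation(r_sample=s) for s in (0, 1000, 6000, 7000)]
        rr = compute_rr(anns, fs=1000.0)
        assert list(rr.valid_mask) == [True, False, True]

    def test_under_two_beats_gives_empty(self):
        assert len(compute_rr([BeatAnnotation(r_sample=5)], 100.0).intervals_ms) == 0


class TestHrvTime:
    def test_constant_series_degenerate(self):
        out = hrv_time(rrs([800.0] * 30))
        assert out["AVNN"] == 800.0
        assert out["SDNN"] == 0.0 and out["RMSSD"] == 0.0
        assert out["pNN50"] == 0.0

    def test_alternating_series_hand_computed(self):
        out = hrv_time(rrs([800.0, 850.0] * 10))
        assert out["RMSSD"] == pytest.approx(50.0)
        assert out["pNN50"] == 0.0  # strict >
        assert out["pNN20"] == 1.0

    def test_sem_identity(self):
        nn = 1000 + 30 * np.random.default_rng(0).standard_normal(64)
        out = hrv_time(rrs(nn))
        assert out["SEM"] == pytest.approx(out["SDNN"] / 8.0, rel=1e-12)

    def test_short_series_missing(self):
        out = hrv_time(rrs([800.0] * 5))
        assert np.isnan(out["AVNN"])


class TestFragmentation:
    def test_ramp_closed_forms(self):
        out = hrv_fragmentation(rrs(800.0 + 10.0 * np.arange(10)))
        assert out["PIP"] == 0.0
        assert out["IALS"] == pytest.approx(1.0 / 9.0)
        assert out["PAS"] == 0.0 and out["PSS"] == 0.0

    def test_perfect_alternation_closed_forms(self):
        n = 10
        out = hrv_fragmentation(rrs([800.0, 850.0] * (n // 2)))
        assert out["PIP"] == pytest.approx((n - 2) / n)
        assert out["PAS"] == 1.0

    @settings(max_examples=60, deadline=None)
    @given(rr_series_strategy)
    def test_fractions_bounded(self, rr):
        out = hrv_fragmentation(rr)
        for key in ("PIP", "PSS", "PAS"):
            assert 0.0 <= out[key] <= 1.0

    def test_pip_decreases_with_increment_autocorrelation(self):
        from vtscreen.synthetic import generate_rr_series
        from conftest import make_profile
        means = []
        for fc in (-0.8, 0.0, 0.8):
            vals = []
            for seed in range(20):
                gt = generate_rr_series(
                    make_profile(frag_coeff=fc, lf_amp=0.0, hf_amp=0.0),
                    0.25, seed=seed)
                vals.append(hrv_fragmentation(rrs(gt.rr_series))["PIP"])
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestFrequency:
    def test_lf_modulation_dominates(self):
        t = np.cumsum(np.full(400, 1.0))
        out = hrv_frequency(rrs(1000 + 50 * np.sin(2 * np.pi * 0.1 * t)))
        assert out["LF_NORM"] > 90.0
        assert out["LF_HF"] > 9.0

    def test_hf_modulation_dominates(self):
        t = np.cumsum(np.full(400, 1.0))
        out = hrv_frequency(rrs(1000 + 50 * np.sin(2 * np.pi * 0.25 * t)))
        assert out["HF_NORM"] > 90.0

    def test_powers_nonnegative_and_short_input_missing(self):
        assert np.isnan(hrv_frequency(rrs([800.0] * 20))["LF_PWR"])  # < 5 min
        t = np.cumsum(np.full(400, 1.0))
        out = hrv_frequency(rrs(1000 + 30 * np.sin(2 * np.pi * 0.17 * t)))
        assert all(out[k] >= 0 for k in ("TOT_PWR", "VLF_PWR", "LF_PWR", "HF_PWR"))


class TestNonlinear:
    @settings(max_examples=60, deadline=None)
    @given(rr_series_strategy)
    def test_sd1_rmssd_identity(self, rr):
        nl, tm = hrv_nonlinear(rr), hrv_time(rr)
        if np.isfinite(nl["SD1"]) and np.isfinite(tm["RMSSD"]):
            assert nl["SD1"] == pytest.approx(tm["RMSSD"] / np.sqrt(2), rel=1e-9)

    def test_constant_series_sampen_missing(self):
        out = hrv_nonlinear(rrs([800.0] * 150))
        assert np.isnan(out["SampEn"])

    def test_sampen_matches_brute_force(self):
        def sampen_ref(x, m, r):
            n = len(x)
            def count(mm):
                tot = 0
                for i in range(n - mm + 1):
                    for j in range(n - mm + 1):
                        if i != j and max(abs(x[i + k] - x[j + k])
                                          for k in range(mm)) <= r:
                            tot += 1
                return tot
            return -np.log(count(m + 1) / count(m))

        x = 1000 + 40 * np.random.default_rng(3).standard_normal(120)
        r = 0.2 * np.std(x, ddof=1)
        assert sample_entropy(x, 2, r) == pytest.approx(
            sampen_ref(list(x), 2, r), rel=1e-5)

    def test_dfa_slopes_on_white_noise(self):
        # oracle (literal per-box loop) gives ~0.61 over boxes 4-11 (known
        # small-scale bias) and ~0.50 over 12-64
        a1, a2 = [], []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(600)
            a1.append(dfa_slope(x, np.arange(4, 12)))
            a2.append(dfa_slope(x, np.arange(12, 65)))
        assert np.mean(a1) == pytest.approx(0.61, abs=0.1)
        assert np.mean(a2) == pytest.approx(0.50, abs=0.12)

    def test_dfa_on_random_walk(self):
        x = np.cumsum(np.random.default_rng(5).standard_normal(2000))
        assert dfa_slope(x, np.arange(12, 65)) > 1.2


class TestMorFeatures:
    def _anns(self, labels):
        out = []
        for i, lab in enumerate(labels):
            fid = {} if lab == "none" else {
                "qrs_on": -40.0, "qrs_off": 40.0, "q_peak": -20.0,
                "s_peak": 20.0, "t_peak": 300.0, "t_off": 400.0, "iso": 0.0}
            out.append(BeatAnnotation(r_sample=1000 + 250 * i,
                                      fiducials=fid, label=lab))
        return out

    def test_ratio_bookkeeping(self):
        labels = ["V"] * 10 + ["N"] * 90
        out = mor_features(self._anns(labels), np.zeros(40000), 250.0)
        assert out["Vratio"] == pytest.approx(0.10)
        total = sum(out[k] for k in
                    ("Nratio", "Sratio", "Vratio", "Fratio", "NoneRatio"))
        assert total == pytest.approx(1.0)

    def test_none_beats_counted_in_ratio_only(self):
        labels = ["N"] * 8 + ["none"] * 2
        out = mor_features(self._anns(labels), np.zeros(40000), 250.0)
        assert out["NoneRatio"] == pytest.approx(0.2)

    def test_too_few_measurable_beats(self):
        out = mor_features(self._anns(["N"] * 3), np.zeros(40000), 250.0)
        assert np.isnan(out["medianQRSint"])
        assert out["Nratio"] == 1.0

    def test_feature_name_inventory(self):
        assert len(HRV_FEATURES) == 23
        assert len(MOR_FEATURES) == 115
        assert len(PI_FEATURES) == 4
        all_names = HRV_FEATURES + MOR_FEATURES + PI_FEATURES
        assert len(set(all_names)) == 142
        for name in ("Vratio", "minRwave", "medianQRSint", "maxQRSArea",
                     "PIP", "IALS", "PSS", "PAS"):
            assert name in all_names


class TestAssemble:
    def _rows(self):
        rng = np.random.default_rng(0)
        rows = []
        for rec in range(2):
            for win in range(4):
                row = {"patient_id": f"p{rec}", "recording_id": f"r{rec}",
                       "window_index": win, "label": rec % 2,
                       "age": 60.0, "sex": "M", "bmi": 25.0, "smoking": False}
                row.update({k: rng.random() for k in HRV_FEATURES})
                row.update({k: rng.random() for k in MOR_FEATURES})
                rows.append(row)
        return rows

    def test_shape_and_columns(self):
        df = assemble_features(self._rows())
        assert len(df) == 8
        feature_cols = [c for c in df.columns
                        if c not in ("patient_id", "recording_id",
                                     "window_index", "label")]
        assert len(feature_cols) == 142

    def test_binary_encodings(self):
        df = assemble_features(self._rows())
        assert set(df["sex"].unique()) <= {0, 1}
        assert set(df["smoking"].unique()) <= {0, 1}

    def test_duplicate_keys_rejected(self):
        rows = self._rows()
        rows.append(dict(rows[0]))
        with pytest.raises(ValueError, match="duplicate"):
            assemble_features(rows)

    def test_features_do_not_read_class_label(self):
        # flipping the recording's class changes only the label column
        from vtscreen.preprocess import apply_filters, split_windows
        from vtscreen.synthetic import generate_rr_series, synthesize_ecg
        from vtscreen import quality
        from vtscreen.features import features_for_recording
        from conftest import make_profile
        from dataclasses import replace

        profile = make_profile(pvc_prob=0.02, noise_level=0.01)
        gt = generate_rr_series(profile, 0.5, seed=31)
        rec, _ = synthesize_ecg(gt, profile, 128.0, seed=32)
        filt = apply_filters(rec)
        windows = split_windows(filt, 30.0)
        det = quality.detect_all_leads(filt)
        quality.score_windows(windows, filt, detections=det)
        rows_c0 = features_for_recording(filt, windows, det)
        flipped = replace(filt, class_label="C1")
        windows2 = split_windows(flipped, 30.0)
        quality.score_windows(windows2, flipped, detections=det)
        rows_c1 = features_for_recording(flipped, windows2, det)
        for a, b in zip(rows_c0, rows_c1):
            assert a["label"] == 0 and b["label"] == 1
            for k in HRV_FEATURES + MOR_FEATURES:
                assert a[k] == b[k] or (np.isnan(a[k]) and np.isnan(b[k]))
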