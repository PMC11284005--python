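"""Shared fixtures: small clean ECG fixtures and session-scoped cohorts.

The heavy synthetic cohorts (used by the end-to-end and parameter-recovery
tests) are built once per session.  Everything is generated at run time
from fixed seeds; nothing is read from disk.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from vtscreen.pipeline import PipelineConfig, extract_cohort_features
from vtscreen.preprocess import apply_filters
from vtscreen.synthetic import PatientProfile, generate_rr_series, synthesize_ecg

logging.getLogger("vtscreen").setLevel(logging.ERROR)

DEFAULT_COHORT_SEED = 1234
NULL_COHORT_SEED = 5678


def make_profile(**kw) -> PatientProfile:
    """A mid-range patient profile; override any field per test."""
    d = dict(
        patient_id="p0", class_label="C0", age=60.0, sex="M", bmi=25.0,
        smoking=False, mean_hr=70.0, rr_sd=40.0, frag_coeff=0.2,
        lf_amp=15.0, hf_amp=10.0, pvc_prob=0.0, pvc_coupling=0.6,
        r_amp=1.0, pvc_width_factor=2.0, noise_level=0.0, n_bad_segments=0,
    )
    d.update(kw)
    return PatientProfile(**d)


@pytest.fixture(scope="session")
def clean_ecg_5min():
    """5-minute clean ECG at 250 Hz with 5% PVCs and known R times."""
    profile = make_profile(pvc_prob=0.05, class_label="C1")
    gt = generate_rr_series(profile, 5.0 / 60.0, seed=7)
    rec, _ = synthesize_ecg(gt, profile, 250.0, seed=8)
    filt = apply_filters(rec)
    truth = np.round(gt.beat_times * 250.0).astype(np.int64)
    return profile, gt, rec, filt, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Default-effect cohort: 40 C1 / 160 C0, 1 h recordings at 128 Hz.

    One retained-window feature table plus per-recording ground truth;
    min_good_windows scales to the 2-windows-per-recording desk format.
    """
    cfg = PipelineConfig(n_c0=160, n_c1=40, duration_h=1.0, fs=128.0,
                         min_good_windows=1, seed=DEFAULT_COHORT_SEED)
    table, manifest, gts = extract_cohort_features(cfg, keep_ground_truth=True)
    return cfg, table, manifest, gts


@pytest.fixture(scope="session")
def null_cohort():
    """effect_size_scale=0 cohort: class labels carry no signal."""
    cfg = PipelineConfig(n_c0=60, n_c1=20, duration_h=1.0, fs=128.0,
                         min_good_windows=1, effect_size_scale=0.0,
                         seed=NULL_COHORT_SEED)
    table, manifest = extract_cohort_features(cfg)
    return cfg, table, manifest


def window_pvc_fractions(cfg, table, gts):
    """Ground-truth PVC fraction for every retained window in the table."""
    span_s = 30.0 * 60.0
    frac = {}
    for profile, rec_id, retained_idx, gt in gts:
        for k in retained_idx:
            sel = (gt.beat_times >= k * span_s) & (gt.beat_times < (k + 1) * span_s)
            if np.sum(sel):
                frac[(rec_id, k)] = float(np.mean(gt.beat_labels[sel] == "V"))
    keys = list(zip(table["recording_id"], table["window_index"]))
    return np.array([frac.get(k, np.nan) for k in keys])
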