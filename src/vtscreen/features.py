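"""Window-level feature extraction: 23 HRV + 115 morphological + 4 PI.

HRV features cover the time domain (AVNN, SDNN, RMSSD, pNN20, pNN50, SEM),
heart-rate fragmentation (PIP, IALS, PSS, PAS), the frequency domain via a
Lomb--Scargle periodogram of the unevenly sampled NN series, and nonlinear
indices (Poincare SD1/SD2, sample entropy, detrended fluctuation slopes).
All valid RR intervals are retained, including those around ectopic beats:
PVC-induced irregularity of the beat-to-beat interval is part of the
signal being measured, not an artefact to remove.

Morphological (MOR) features summarise 22 per-beat waveform measures by
mean/median/min/max/IQR per window (110 values) plus the five beat-class
ratios.  Missing values are explicit NaN, never silent zeros, and nothing
in this module reads the class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

from .beats import BeatAnnotation
from .preprocess import EcgRecording, EcgWindow

RR_VALID_MS = (300.0, 2500.0)

HRV_TIME = ["AVNN", "SDNN", "RMSSD", "pNN20", "pNN50", "SEM"]
HRV_FRAG = ["PIP", "IALS", "PSS", "PAS"]
HRV_FREQ = ["TOT_PWR", "VLF_PWR", "LF_PWR", "HF_PWR", "LF_HF", "LF_NORM", "HF_NORM"]
HRV_NONLIN = ["SD1", "SD2", "SD1_SD2", "SampEn", "DFA_alpha1", "DFA_alpha2"]
HRV_FEATURES = HRV_TIME + HRV_FRAG + HRV_FREQ + HRV_NONLIN

MOR_MEASURES = [
    "Pdur", "PRint", "QRSint", "QTint", "QTc_Bazett", "QTc_Fridericia",
    "JTint", "Tdur", "Pamp", "Qamp", "Rwave", "Samp", "Tamp", "QRSArea",
    "Tarea", "Parea", "STlevel", "RslopeUp", "RslopeDown", "RSamp",
    "TRratio", "Jamp",
]
MOR_STATS = ["mean", "median", "min", "max", "iqr"]
RATIO_FEATURES = ["Nratio", "Sratio", "Vratio", "Fratio", "NoneRatio"]
MOR_FEATURES = [f"{s}{m}" for m in MOR_MEASURES for s in MOR_STATS] + RATIO_FEATURES

PI_FEATURES = ["age", "sex", "bmi", "smoking"]
KEY_COLUMNS = ["patient_id", "recording_id", "window_index"]

BANDS = {"VLF": (0.0033, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.4)}


@dataclass
class RRSeries:
    """Beat times (s), successive intervals (ms), labels, validity mask."""

    times_s: np.ndarray
    intervals_ms: np.ndarray
    labels: np.ndarray
    valid_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.valid_mask is None:
            self.valid_mask = (self.intervals_ms >= RR_VALID_MS[0]) & (
                self.intervals_ms <= RR_VALID_MS[1])

    @property
    def valid(self) -> np.ndarray:
        return self.intervals_ms[self.valid_mask]


def compute_rr(annotations: list[BeatAnnotation], fs: float,
               r_times_s: np.ndarray | None = None) -> RRSeries:
    """Successive R-R intervals with the [300, 2500] ms range filter.

    Interval k runs from beat k to beat k+1 and carries the label of the
    beat that ends it (so a PVC's own premature interval is labelled V).
    ``r_times_s`` optionally supplies sub-sample beat times (seconds), as
    from ``beats.refine_r_times``; otherwise integer sample indices are
    used.
    """
    labels = np.array([a.label for a in annotations], dtype="<U4")
    if r_times_s is not None:
        t = np.asarray(r_times_s, dtype=float)
    else:
        t = np.array([a.r_sample for a in annotations], dtype=float) / fs
    if len(t) < 2:
        empty = np.array([])
        return RRSeries(empty, empty, np.array([], dtype="<U4"))
    iv = np.diff(t) * 1000.0
    return RRSeries(times_s=t[1:], intervals_ms=iv, labels=labels[1:])


def _nan_set(names: list[str]) -> dict:
    return {k: float("nan") for k in names}


def hrv_time(rr: RRSeries) -> dict:
    """Time-domain HRV.  pNNx uses a strict > x ms criterion."""
    nn = rr.valid
    if len(nn) < 10:
        return _nan_set(HRV_TIME)
    d = np.abs(np.diff(nn))
    sdnn = float(np.std(nn, ddof=1))
    return {
        "AVNN": float(np.mean(nn)),
        "SDNN": sdnn,
        "RMSSD": float(np.sqrt(np.mean(np.diff(nn) ** 2))) if len(nn) > 1 else float("nan"),
        "pNN20": float(np.mean(d > 20.0)) if len(d) else float("nan"),
        "pNN50": float(np.mean(d > 50.0)) if len(d) else float("nan"),
        "SEM": sdnn / np.sqrt(len(nn)),
    }


def _increment_signs(nn: np.ndarray) -> np.ndarray:
    return np.sign(np.diff(nn)).astype(int)


def hrv_fragmentation(rr: RRSeries) -> dict:
    """Heart-rate fragmentation: PIP, IALS, PSS, PAS.

    Computed on the signs of successive NN increments; a zero increment is
    treated as a sign change.  Runs (acceleration/deceleration segments)
    and alternation stretches are counted over increments, and fractions
    are relative to the number of increments — under this convention the
    closed forms hold exactly: PIP(ramp)=0, PIP(alternation of n
    intervals)=(n-2)/n, PAS(alternation)=1, IALS(ramp)=1/(n-1).
    """
    nn = rr.valid
    n = len(nn)
    if n < 10:
        return _nan_set(HRV_FRAG)
    s = _increment_signs(nn)
    m = len(s)  # = n - 1 increments

    # inflection points: sign differs from predecessor (zeros always flip)
    change = (s[1:] != s[:-1]) | (s[1:] == 0) | (s[:-1] == 0)
    pip = float(np.sum(change)) / n

    # maximal runs of constant nonzero sign
    run_lengths = []
    cur_sign, cur_len = 0, 0
    for v in s:
        if v != 0 and v == cur_sign:
            cur_len += 1
        else:
            if cur_len:
                run_lengths.append(cur_len)
            cur_sign, cur_len = v, (1 if v != 0 else 0)
    if cur_len:
        run_lengths.append(cur_len)
    ials = 1.0 / float(np.mean(run_lengths)) if run_lengths else float("nan")
    short = sum(L for L in run_lengths if L < 3)
    pss = short / m

    # maximal strictly alternating stretches (s[i] == -s[i-1], nonzero)
    alt_in_long = 0
    i = 0
    while i < m:
        if s[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < m and s[j + 1] == -s[j] and s[j + 1] != 0:
            j += 1
        length = j - i + 1
        if length >= 4:
            alt_in_long += length
        i = j + 1
    pas = alt_in_long / m
    return {"PIP": pip, "IALS": ials, "PSS": pss, "PAS": pas}


def hrv_frequency(rr: RRSeries, n_freq: int = 256) -> dict:
    """Band powers from a Lomb--Scargle periodogram of the NN series.

    The unevenly sampled NN series is analysed directly (no resampling, so
    no interpolation artefacts at high ectopy).  The periodogram is scaled
    to a one-sided PSD in ms^2/Hz and band powers are trapezoidal
    integrals over VLF 0.0033-0.04, LF 0.04-0.15, HF 0.15-0.4 Hz.
    """
    mask = rr.valid_mask
    nn = rr.intervals_ms[mask]
    t = rr.times_s[mask]
    if len(nn) < 10 or (t[-1] - t[0]) < 300.0:
        return _nan_set(HRV_FREQ)
    y = nn - np.mean(nn)
    freqs = np.linspace(BANDS["VLF"][0], BANDS["HF"][1], n_freq)
    pgram = lombscargle(t, y, 2 * np.pi * freqs)
    span = t[-1] - t[0]
    psd = pgram * 2.0 * span / len(nn)

    def band_power(lo: float, hi: float) -> float:
        sel = (freqs >= lo) & (freqs <= hi)
        if np.sum(sel) < 2:
            return 0.0
        return float(np.trapezoid(psd[sel], freqs[sel]))

    vlf = band_power(*BANDS["VLF"])
    lf = band_power(*BANDS["LF"])
    hf = band_power(*BANDS["HF"])
    denom = lf + hf
    return {
        "TOT_PWR": vlf + lf + hf,
        "VLF_PWR": vlf,
        "LF_PWR": lf,
        "HF_PWR": hf,
        "LF_HF": lf / hf if hf > 0 else float("nan"),
        "LF_NORM": 100.0 * lf / denom if denom > 0 else float("nan"),
        "HF_NORM": 100.0 * hf / denom if denom > 0 else float("nan"),
    }


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) with Chebyshev distance, excluding self-matches."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if r is None:
        r = 0.2 * np.std(x, ddof=1)
    if n < m + 2 or not np.isfinite(r) or r <= 0:
        return float("nan")

    # pairwise Chebyshev distances built incrementally: the m-embedding
    # distance is the running maximum of shifted scalar distance matrices
    # (float32: the tolerance comparison is far coarser than the precision)
    x = x.astype(np.float32)
    r = np.float32(r)
    d0 = np.abs(x[:, None] - x[None, :])
    dm = d0[:n - m + 1, :n - m + 1].copy()
    for k in range(1, m):
        np.maximum(dm, d0[k:k + n - m + 1, k:k + n - m + 1], out=dm)
    b = int(np.sum(dm <= r)) - dm.shape[0]
    dm1 = np.maximum(dm[:n - m, :n - m], d0[m:, m:])
    a = int(np.sum(dm1 <= r)) - dm1.shape[0]
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def dfa_slope(x: np.ndarray, scales: np.ndarray) -> float:
    """Detrended fluctuation analysis slope over the given box sizes."""
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - np.mean(x))
    fs_vals, used = [], []
    for n in scales:
        k = len(y) // n
        if k < 2:
            continue
        seg = y[:k * n].reshape(k, n)
        t = np.arange(n)
        t_c = t - t.mean()
        denom = float(np.sum(t_c ** 2))
        slope = seg @ t_c / denom
        resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * t_c
        fs_vals.append(np.sqrt(np.mean(resid ** 2)))
        used.append(n)
    if len(used) < 2 or np.min(fs_vals) <= 0:
        return float("nan")
    coef = np.polyfit(np.log(used), np.log(fs_vals), 1)
    return float(coef[0])


def hrv_nonlinear(rr: RRSeries) -> dict:
    """Poincare descriptors, sample entropy, and DFA slopes.

    SD1 is sqrt(mean(dNN^2)/2), i.e. exactly RMSSD/sqrt(2); SD2 follows
    from 2*SDNN^2 - SD1^2.  SampEn uses m=2, r=0.2*SDNN; DFA alpha1 over
    boxes 4-11, alpha2 over 12-64.  SampEn/DFA need >= 100 intervals.
    """
    nn = rr.valid
    if len(nn) < 10:
        return _nan_set(HRV_NONLIN)
    d = np.diff(nn)
    sd1 = float(np.sqrt(np.mean(d ** 2) / 2.0))
    sdnn = float(np.std(nn, ddof=1))
    sd2sq = 2.0 * sdnn ** 2 - sd1 ** 2
    sd2 = float(np.sqrt(max(sd2sq, 0.0)))
    out = {
        "SD1": sd1,
        "SD2": sd2,
        "SD1_SD2": sd1 / sd2 if sd2 > 0 else float("nan"),
        "SampEn": float("nan"),
        "DFA_alpha1": float("nan"),
        "DFA_alpha2": float("nan"),
    }
    if len(nn) >= 100:
        out["SampEn"] = sample_entropy(nn, m=2, r=0.2 * sdnn)
        out["DFA_alpha1"] = dfa_slope(nn, np.arange(4, 12))
        out["DFA_alpha2"] = dfa_slope(nn, np.arange(12, 65))
    return out


def hrv_features(rr: RRSeries) -> dict:
    out = {}
    out.update(hrv_time(rr))
    out.update(hrv_fragmentation(rr))
    out.update(hrv_frequency(rr))
    out.update(hrv_nonlinear(rr))
    return out


# ---------------------------------------------------------------------------
# morphological features
# ---------------------------------------------------------------------------

def _beat_measures(ann: BeatAnnotation, signal: np.ndarray, fs: float,
                   rr_prev_ms: float) -> dict:
    """The 22 per-beat waveform measures (ms, mV, mV*ms) from fiducials."""
    f = ann.fiducials
    iso = f["iso"]
    r = ann.r_sample
    n = len(signal)
    scale = fs / 1000.0

    def samp_at(ms_off: float) -> int:
        s = r + int(round(ms_off * scale))
        return 0 if s < 0 else (n - 1 if s >= n else s)

    def amp_at(ms_off: float | None) -> float:
        if ms_off is None:
            return float("nan")
        return float(signal[samp_at(ms_off)]) - iso

    def area(ms_a: float | None, ms_b: float | None) -> float:
        if ms_a is None or ms_b is None:
            return float("nan")
        a, b = samp_at(ms_a), samp_at(ms_b)
        if b <= a:
            return float("nan")
        seg = np.abs(signal[a:b + 1] - iso)
        # trapezoidal area between signal and isoelectric line, mV*ms
        return float(seg.sum() - 0.5 * (seg[0] + seg[-1])) * 1000.0 / fs

    qrs_on, qrs_off = f["qrs_on"], f["qrs_off"]
    t_pk, t_off = f["t_peak"], f["t_off"]
    p_on, p_pk, p_off = f.get("p_on"), f.get("p_peak"), f.get("p_off")

    qt = t_off - qrs_on
    rr_s = rr_prev_ms / 1000.0 if np.isfinite(rr_prev_ms) and rr_prev_ms > 0 else float("nan")
    tdur = 2.0 * (t_off - t_pk)

    a, b = samp_at(qrs_on), samp_at(qrs_off)
    qseg = signal[max(a - 1, 0):b + 2]
    dseg = (qseg[1:] - qseg[:-1]) * fs  # mV/s
    r_col = samp_at(0.0) - max(a - 1, 0)
    up = float(dseg[:max(r_col, 1)].max()) if r_col >= 1 else float("nan")
    down = float(dseg[r_col:].min()) if r_col < len(dseg) else float("nan")

    rwave = amp_at(0.0)
    s_amp = amp_at(f["s_peak"])
    t_amp = amp_at(t_pk)
    return {
        "Pdur": (p_off - p_on) if p_on is not None else float("nan"),
        "PRint": (qrs_on - p_on) if p_on is not None else float("nan"),
        "QRSint": qrs_off - qrs_on,
        "QTint": qt,
        "QTc_Bazett": qt / np.sqrt(rr_s) if np.isfinite(rr_s) else float("nan"),
        "QTc_Fridericia": qt / np.cbrt(rr_s) if np.isfinite(rr_s) else float("nan"),
        "JTint": t_off - qrs_off,
        "Tdur": tdur,
        "Pamp": amp_at(p_pk),
        "Qamp": amp_at(f["q_peak"]),
        "Rwave": rwave,
        "Samp": s_amp,
        "Tamp": t_amp,
        "QRSArea": area(qrs_on, qrs_off),
        "Tarea": area(t_pk - (t_off - t_pk), t_off),
        "Parea": area(p_on, p_off),
        "STlevel": amp_at(qrs_off + 40.0),
        "RslopeUp": up,
        "RslopeDown": down,
        "RSamp": rwave - s_amp,
        "TRratio": t_amp / rwave if rwave not in (0.0,) else float("nan"),
        "Jamp": amp_at(qrs_off),
    }


def mor_features(annotations: list[BeatAnnotation], signal: np.ndarray,
                 fs: float, min_measurable: int = 5) -> dict:
    """Window-level morphological features: 5 stats x 22 measures + ratios.

    Beats labelled ``none`` are excluded from waveform statistics but
    counted in ``NoneRatio``; each statistic is taken over the beats where
    the measure is present.  With fewer than ``min_measurable`` usable
    beats the waveform summaries are missing but ratios are still
    computed.
    """
    out = {k: float("nan") for k in MOR_FEATURES}
    n_beats = len(annotations)
    if n_beats == 0:
        return out
    labels = np.array([a.label for a in annotations])
    for name, code in (("Nratio", "N"), ("Sratio", "S"), ("Vratio", "V"),
                       ("Fratio", "F"), ("NoneRatio", "none")):
        out[name] = float(np.mean(labels == code))

    usable = [a for a in annotations if a.label != "none" and a.fiducials]
    if len(usable) < min_measurable:
        return out
    r = np.array([a.r_sample for a in usable], dtype=float)
    rr_prev = np.concatenate([[np.nan], np.diff(r) / fs * 1000.0])
    rows = [_beat_measures(a, signal, fs, rp) for a, rp in zip(usable, rr_prev)]
    for m in MOR_MEASURES:
        vals = np.array([row[m] for row in rows], dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        out[f"mean{m}"] = float(np.mean(vals))
        out[f"median{m}"] = float(np.median(vals))
        out[f"min{m}"] = float(np.min(vals))
        out[f"max{m}"] = float(np.max(vals))
        q1, q3 = np.percentile(vals, [25, 75])
        out[f"iqr{m}"] = float(q3 - q1)
    return out


def window_features(window: EcgWindow, recording: EcgRecording,
                    annotations: list[BeatAnnotation]) -> dict:
    """All HRV + MOR features for one window (annotations window-relative)."""
    from .beats import refine_r_times

    fs = recording.fs
    lead_full = recording.signal[window.lead_used or 0]
    r_times = refine_r_times(lead_full, fs,
                             np.array([a.r_sample for a in annotations],
                                      dtype=np.int64))
    rr = compute_rr(annotations, fs, r_times_s=r_times)
    feats = hrv_features(rr)
    lead = recording.signal[window.lead_used or 0,
                            window.start_sample:window.end_sample]
    local = [BeatAnnotation(r_sample=a.r_sample - window.start_sample,
                            fiducials=a.fiducials, label=a.label)
             for a in annotations]
    feats.update(mor_features(local, lead, fs))
    return feats


def assemble_features(rows: list[dict]) -> pd.DataFrame:
    """Stack per-window feature dicts into the model-ready table.

    One row per retained window, keyed by (patient_id, recording_id,
    window_index); PI fields broadcast from the recording with sex and
    smoking encoded {0,1}.  Duplicate keys are an error.
    """
    if not rows:
        return pd.DataFrame(columns=KEY_COLUMNS + ["label"] + PI_FEATURES
                            + HRV_FEATURES + MOR_FEATURES)
    df = pd.DataFrame(rows)
    if df.duplicated(subset=KEY_COLUMNS).any():
        raise ValueError("duplicate (patient, recording, window) keys")
    if df["sex"].dtype == object:
        df["sex"] = (df["sex"] == "M").astype(int)
    df["smoking"] = df["smoking"].astype(int)
    cols = KEY_COLUMNS + ["label"] + PI_FEATURES + HRV_FEATURES + MOR_FEATURES
    df = df[cols].sort_values(KEY_COLUMNS).reset_index(drop=True)
    return df


def features_for_recording(recording: EcgRecording, retained: list[EcgWindow],
                           detections) -> list[dict]:
    """Feature rows for every retained window of one recording.

    ``detections`` is the (primary, secondary) pair of per-lead detection
    lists on the full (filtered) recording, as produced by
    ``quality.detect_all_leads``; each window is delineated and classified
    on its selected lead only, with beats in locally low-quality context
    (detector disagreement, e.g. inside a noise burst) labelled ``none``.
    """
    from . import beats as _beats

    det_primary, det_secondary = detections
    out = []
    fs = recording.fs
    for w in retained:
        lead_idx = w.lead_used or 0
        lead = recording.signal[lead_idx]
        det = det_primary[lead_idx]
        det_w = det[(det >= w.start_sample) & (det < w.end_sample)]
        local = det_w - w.start_sample
        det_b = det_secondary[lead_idx]
        det_b = det_b[(det_b >= w.start_sample) & (det_b < w.end_sample)]
        ctx = _beats.local_bsqi_context(det_w, det_b, fs)
        seg = lead[w.start_sample:w.end_sample]
        anns = _beats.delineate(seg, fs, local)
        anns = _beats.classify_beats(seg, fs, anns, context_valid=ctx)
        for a in anns:  # back to recording coordinates
            a.r_sample += w.start_sample
        row = {
            "patient_id": recording.patient_id,
            "recording_id": recording.recording_id,
            "window_index": w.window_index,
            "label": 1 if recording.class_label == "C1" else 0,
            "age": recording.pi.get("age", float("nan")),
            "sex": recording.pi.get("sex", "F"),
            "bmi": recording.pi.get("bmi", float("nan")),
            "smoking": bool(recording.pi.get("smoking", False)),
        }
        row.update(window_features(w, recording, anns))
        out.append(row)
    return out
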