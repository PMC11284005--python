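"""R-peak detection, wave delineation, and rule-based beat classification.

Two algorithmically independent QRS detectors are provided: an energy
detector in the Pan--Tompkins family (band-pass, differentiate, square,
moving-window integrate, adaptive threshold) and a curve-length-transform
detector with a fixed whole-segment threshold.  Their agreement is the
substrate of the bsqi quality index; the primary detector also feeds the
feature pipeline.

Beats are delineated into fiducial points (QRS on/offset by slope
threshold, T-end by the tangent method, P as the largest pre-QRS positive
bump) and classified into {N, S, V, F, none} with a deterministic rule set
built on QRS duration, prematurity, and correlation with a running
template of the dominant morphology.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

REFRACTORY_S = 0.25

#: classification thresholds (configurable via classify_beats kwargs)
WIDE_QRS_MS = 120.0
PREMATURITY_THR = 0.90
V_CORR_THR = 0.8
F_CORR_THR = 0.95


@dataclass
class BeatAnnotation:
    """One beat: R sample, optional fiducials, class label, context scores.

    Fiducial sample indices are ``None`` when absent (edge beats, missing
    P wave).  ``prematurity`` is RR_prev / local median RR.
    """

    r_sample: int
    fiducials: dict = field(default_factory=dict)
    label: str = "none"
    template_corr: float = float("nan")
    prematurity: float = float("nan")

    def fiducial(self, name: str):
        return self.fiducials.get(name)

    @property
    def qrs_duration_ms(self) -> float:
        on, off = self.fiducials.get("qrs_on"), self.fiducials.get("qrs_off")
        if on is None or off is None:
            return float("nan")
        return float(off - on)  # stored in ms by delineate


def _refine(signal: np.ndarray, candidates: np.ndarray, fs: float,
            pre_s: float, post_s: float) -> np.ndarray:
    """Snap candidate detections to the local absolute maximum of `signal`."""
    n = len(signal)
    out = np.empty(len(candidates), dtype=np.int64)
    pre, post = int(pre_s * fs), int(post_s * fs)
    for k, c in enumerate(candidates):
        lo, hi = max(0, c - pre), min(n, c + post + 1)
        out[k] = lo + int(np.argmax(np.abs(signal[lo:hi])))
    return out


def _dedupe(idx: np.ndarray, amps: np.ndarray, fs: float) -> np.ndarray:
    """Enforce the refractory period, keeping the larger-amplitude detection."""
    if len(idx) == 0:
        return idx
    order = np.argsort(idx, kind="stable")
    idx, amps = idx[order], amps[order]
    keep: list[int] = []
    ref = REFRACTORY_S * fs
    for i in range(len(idx)):
        if keep and idx[i] - idx[keep[-1]] < ref:
            if amps[i] > amps[keep[-1]]:
                keep[-1] = i
        else:
            keep.append(i)
    return idx[keep]


def detect_qrs_primary(signal: np.ndarray, fs: float) -> np.ndarray:
    """Energy-based QRS detector (Pan--Tompkins family).

    Band-pass 5--15 Hz, differentiate, square, moving-window integrate
    (150 ms), then an adaptive signal/noise threshold with a 250 ms
    refractory period.  All thresholds are relative, so detections are
    invariant to amplitude scaling.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    if np.ptp(signal) == 0:
        return np.array([], dtype=np.int64)
    high = min(15.0, 0.45 * fs)
    sos = sps.butter(2, [5.0, high], btype="bandpass", fs=fs, output="sos")
    f = sps.sosfiltfilt(sos, signal)
    d = np.diff(f, prepend=f[0])
    sq = d * d
    win = max(1, int(0.150 * fs))
    integ = uniform_filter1d(sq, size=win)
    cand, _ = sps.find_peaks(integ, distance=max(1, int(REFRACTORY_S * fs)))
    if len(cand) == 0:
        return np.array([], dtype=np.int64)
    # adaptive signal/noise running estimates (classic 0.125 update)
    heights = integ[cand]
    spki = float(np.percentile(heights, 90))
    npki = float(np.percentile(heights, 10))
    accepted = []
    last = cand[0]
    for c, h in zip(cand, heights):
        thr = npki + 0.25 * (spki - npki)
        if h > thr:
            accepted.append(c)
            # slew-limited update: a noise burst must not pump the signal
            # level so high that ordinary beats are rejected forever after
            spki = 0.125 * min(h, 4.0 * spki) + 0.875 * spki
            last = c
        else:
            npki = 0.125 * h + 0.875 * npki
            if c - last > 3.0 * fs:      # lost lock: relax toward noise level
                spki = 0.5 * spki + 0.5 * npki
                last = c
    if not accepted:
        return np.array([], dtype=np.int64)
    r = _refine(f, np.asarray(accepted), fs, 0.15, 0.15)
    return np.unique(_dedupe(r, np.abs(f[r]), fs))


def detect_qrs_secondary(signal: np.ndarray, fs: float) -> np.ndarray:
    """Curve-length-transform QRS detector with fixed-window thresholding.

    The curve length (moving sum of |dy| over 130 ms) peaks sharply at QRS
    complexes.  A single fixed threshold is derived from whole-segment
    order statistics: max(2 x the transform's lower quartile, 0.4 x the
    lower quartile of its 4-s block maxima).  Lower quartiles anchor both
    terms to the quieter part of the segment, so noise bursts occupying
    even most of the recording cannot silence detection elsewhere; on
    broadband noise the transform concentrates near its median, so the
    first term silences the detector -- deliberately
    different failure behaviour from the primary detector, which is what
    makes their agreement informative.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    if np.ptp(signal) == 0:
        return np.array([], dtype=np.int64)
    adiff = np.abs(np.diff(signal, prepend=signal[0]))
    win = max(1, int(0.130 * fs))
    cl = uniform_filter1d(adiff, size=win) * win
    block = max(1, int(4.0 * fs))
    n_blocks = len(cl) // block
    block_max = cl[:n_blocks * block].reshape(n_blocks, block).max(axis=1) \
        if n_blocks >= 1 else np.array([cl.max()])
    # lower quartiles keep both terms anchored to the quieter part of the
    # segment, so a long noise burst cannot silence detection elsewhere
    thr = max(2.0 * float(np.percentile(cl, 25)),
              0.4 * float(np.percentile(block_max, 25)))
    cand, _ = sps.find_peaks(cl, distance=max(1, int(REFRACTORY_S * fs)), height=thr)
    if len(cand) == 0:
        return np.array([], dtype=np.int64)
    r = _refine(signal, cand, fs, 0.10, 0.10)
    return np.unique(_dedupe(r, np.abs(signal[r]), fs))


# ---------------------------------------------------------------------------
# delineation
# ---------------------------------------------------------------------------

_SLOPE_FRAC = 0.05  # onset/offset: |slope| falls below 5% of peak slope


def delineate(signal: np.ndarray, fs: float, r_samples: np.ndarray) -> list[BeatAnnotation]:
    """Locate per-beat fiducial points around each R peak.

    QRS on/offset: from the maximal up/down-slope flank, walk outward until
    the absolute derivative stays below 5% of the beat's peak slope for two
    consecutive samples (the two-sample run skips the zero-slope instants at
    the Q/S troughs).  T-end: tangent method in the 80--400 ms post-QRS
    window.  P: largest positive smoothed bump in the 200 ms pre-QRS window,
    absent when below an amplitude floor or overlapping the previous T wave.

    Fiducials are stored in the ``fiducials`` dict in *milliseconds relative
    to the R sample* for durations-friendly arithmetic, except that callers
    can recover absolute samples via ``r_sample``.  Beats too close to the
    segment edge get no fiducials and keep label ``none``.
    """
    signal = np.asarray(signal, dtype=float)
    r_samples = np.asarray(r_samples, dtype=np.int64)
    n = len(signal)
    anns = [BeatAnnotation(r_sample=int(r)) for r in r_samples]
    if len(r_samples) == 0:
        return anns

    half = int(0.55 * fs)
    ok = (r_samples - half >= 0) & (r_samples + half < n)
    idx_ok = np.flatnonzero(ok)
    if len(idx_ok) == 0:
        return anns
    r_ok = r_samples[idx_ok]

    rel = np.arange(-half, half + 1)
    seg = signal[r_ok[:, None] + rel[None, :]]             # beats x L
    # slope search runs on a 20 ms moving average: it nulls 50 Hz powerline
    # residue exactly and suppresses broadband noise while leaving the QRS
    # flanks (sigma ~10 ms) nearly intact
    seg_s = uniform_filter1d(seg, size=max(2, int(round(0.02 * fs))), axis=1)
    dseg = np.gradient(seg_s, axis=1) * fs / 1000.0        # mV/ms
    c0 = half                                              # column of R
    ms = 1000.0 / fs

    def col(ms_off: float) -> int:
        return c0 + int(round(ms_off / ms))

    cols = np.arange(seg.shape[1])

    # --- QRS flanks & peak slope in R +/- 100 ms
    a, b = col(-100), col(100)
    flank = np.abs(dseg[:, a:b + 1])
    mslope = flank.max(axis=1)
    mslope[mslope == 0] = np.finfo(float).tiny
    up = a + np.argmax(dseg[:, a:c0 + 1], axis=1)          # max upslope before R
    down = c0 + np.argmax(-dseg[:, c0:b + 1], axis=1)      # max downslope after R

    # threshold: 5% of the beat's peak slope, floored at the segment's
    # baseline slope level (residual noise / powerline would otherwise keep
    # |d| above the pure 5% rule everywhere)
    # the 25th percentile of |d| tracks the baseline noise slope without
    # being dragged up by neighbouring beats inside the segment
    noise_floor = 2.5 * np.percentile(np.abs(dseg), 25, axis=1)
    thr = np.maximum(_SLOPE_FRAC * mslope, noise_floor)
    below = np.abs(dseg) < thr[:, None]
    below2 = below & np.roll(below, 1, axis=1)             # two-sample run (this & prev)
    below2f = below & np.roll(below, -1, axis=1)           # this & next

    lo_lim, hi_lim = col(-160), col(160)
    m_on = below2 & (cols[None, :] <= up[:, None]) & (cols[None, :] >= lo_lim)
    any_on = m_on.any(axis=1)
    qrs_on = np.where(any_on,
                      m_on.shape[1] - 1 - np.argmax(m_on[:, ::-1], axis=1),
                      lo_lim)
    m_off = below2f & (cols[None, :] >= down[:, None]) & (cols[None, :] <= hi_lim)
    any_off = m_off.any(axis=1)
    qrs_off = np.where(any_off, np.argmax(m_off, axis=1), hi_lim)

    iso = seg[np.arange(len(r_ok)), qrs_on]                # isoelectric level at QRS onset

    # --- Q and S troughs
    q_pk = np.empty(len(r_ok), dtype=np.int64)
    s_pk = np.empty(len(r_ok), dtype=np.int64)
    for i in range(len(r_ok)):
        q_pk[i] = qrs_on[i] + np.argmin(seg[i, qrs_on[i]:c0 + 1])
        s_pk[i] = c0 + np.argmin(seg[i, c0:qrs_off[i] + 1])

    # --- T wave: peak in [QRS_off + 80, QRS_off + 400] ms, tangent end
    t_pk = np.empty(len(r_ok), dtype=np.int64)
    t_off = np.empty(len(r_ok), dtype=np.int64)
    w400 = int(round(400.0 / ms))
    w80 = int(round(80.0 / ms))
    L = seg.shape[1]
    for i in range(len(r_ok)):
        lo = min(qrs_off[i] + w80, L - 2)
        hi = min(qrs_off[i] + w400, L - 1)
        dev = np.abs(seg[i, lo:hi + 1] - iso[i])
        tp = lo + int(np.argmax(dev))
        t_pk[i] = tp
        # steepest return-to-baseline flank after the T peak
        hi2 = min(tp + int(round(200.0 / ms)) + 1, L)
        sl = dseg[i, tp:hi2]
        if len(sl) < 2:
            t_off[i] = tp
            continue
        sgn = np.sign(seg[i, tp] - iso[i]) or 1.0
        j = tp + int(np.argmax(-sgn * sl))                 # steepest opposite slope
        slope = dseg[i, j]
        if sgn * slope >= 0 or abs(slope) < 1e-9:
            t_off[i] = min(tp + int(round(160.0 / ms)), L - 1)
        else:
            dt = (seg[i, j] - iso[i]) / -slope             # ms to baseline crossing
            t_off[i] = min(j + int(round(max(0.0, dt) / ms)), L - 1)

    # --- P wave: largest positive smoothed bump in the 200 ms pre-QRS window,
    # clipped to start after the previous beat's T end (premature beats).
    sm = uniform_filter1d(seg, size=max(1, int(0.02 * fs)), axis=1)
    p_floor = 0.05                                         # mV above isoelectric
    prev_t_off_abs = np.full(len(r_ok), -10**9, dtype=np.int64)
    prev_t_off_abs[1:] = r_ok[:-1] + (t_off[:-1] - c0)
    p_pk = np.full(len(r_ok), -1, dtype=np.int64)
    p_on = np.full(len(r_ok), -1, dtype=np.int64)
    p_off_a = np.full(len(r_ok), -1, dtype=np.int64)
    w200 = int(round(200.0 / ms))
    w30 = int(round(30.0 / ms))
    for i in range(len(r_ok)):
        lo = max(qrs_on[i] - w200, 0)
        guard = prev_t_off_abs[i] + int(round(60.0 / ms)) - (r_ok[i] - c0)
        lo = max(lo, guard)
        hi = qrs_on[i] - w30
        if hi <= lo:
            continue
        bump = sm[i, lo:hi + 1] - iso[i]
        k = int(np.argmax(bump))
        # a true P bump peaks inside the window; a neighbouring wave's tail
        # decaying through it peaks at the boundary
        if bump[k] < p_floor or k == 0 or k == len(bump) - 1:
            continue
        pk = lo + k
        thr_amp = 0.15 * bump[k]
        left = np.flatnonzero(bump[:k + 1] < thr_amp)
        right = np.flatnonzero(bump[k:] < thr_amp)
        p_pk[i] = pk
        p_on[i] = lo + (left[-1] if len(left) else 0)
        p_off_a[i] = pk + (right[0] if len(right) else (hi - pk))

    for j, i in enumerate(idx_ok):
        f = {
            "qrs_on": (qrs_on[j] - c0) * ms,
            "qrs_off": (qrs_off[j] - c0) * ms,
            "q_peak": (q_pk[j] - c0) * ms,
            "s_peak": (s_pk[j] - c0) * ms,
            "t_peak": (t_pk[j] - c0) * ms,
            "t_off": (t_off[j] - c0) * ms,
            "iso": float(iso[j]),
        }
        if p_pk[j] >= 0:
            f["p_peak"] = (p_pk[j] - c0) * ms
            f["p_on"] = (p_on[j] - c0) * ms
            f["p_off"] = (p_off_a[j] - c0) * ms
        anns[i].fiducials = f
    return anns


# ---------------------------------------------------------------------------
# beat classification
# ---------------------------------------------------------------------------

@dataclass
class BeatTemplate:
    """Running unit-energy template of the dominant QRS morphology."""

    waveform: np.ndarray
    update_count: int = 0

    @staticmethod
    def _norm(x: np.ndarray) -> np.ndarray:
        x = x - x.mean()
        e = float(np.linalg.norm(x))
        return x / e if e > 0 else x

    def corr(self, beat: np.ndarray) -> float:
        return float(np.dot(self.waveform, self._norm(beat)))

    def update(self, beat: np.ndarray, alpha: float = 0.05) -> None:
        self.waveform = self._norm((1 - alpha) * self.waveform + alpha * self._norm(beat))
        self.update_count += 1


def _medoid(beats: np.ndarray) -> np.ndarray:
    x = beats - beats.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(x, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    u = x / nrm
    c = u @ u.T
    return beats[int(np.argmax(c.sum(axis=1)))]


def refine_r_times(signal: np.ndarray, fs: float,
                   r_samples: np.ndarray) -> np.ndarray:
    """Sub-sample R times (seconds) by parabolic peak interpolation.

    At Holter sampling rates (128 Hz) the one-sample quantization of R
    times is ~8 ms — enough to flip the sign of small RR increments and
    blur fragmentation metrics.  Fitting a parabola through the three
    samples around each peak recovers the vertex to a fraction of a
    sample.
    """
    r = np.asarray(r_samples, dtype=np.int64)
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    inner = (r >= 1) & (r < n - 1)
    delta = np.zeros(len(r))
    ri = r[inner]
    y0, y1, y2 = signal[ri - 1], signal[ri], signal[ri + 1]
    denom = y0 - 2.0 * y1 + y2
    ok = np.abs(denom) > 1e-12
    d = np.zeros(len(ri))
    d[ok] = 0.5 * (y0[ok] - y2[ok]) / denom[ok]
    delta[inner] = np.clip(d, -0.5, 0.5)
    return (r + delta) / fs


def local_bsqi_context(det_primary: np.ndarray, det_secondary: np.ndarray,
                       fs: float, tol_ms: float = 150.0,
                       halfwidth_s: float = 5.0,
                       threshold: float = 0.8) -> np.ndarray:
    """Per-beat validity from localized inter-detector agreement.

    For each primary detection, the F1 agreement of the two detectors is
    evaluated over a +/- ``halfwidth_s`` neighbourhood; beats sitting in a
    neighbourhood below ``threshold`` (e.g. inside a noise burst that did
    not sink the whole window) are flagged invalid and will be labelled
    ``none`` by :func:`classify_beats`.
    """
    a = np.asarray(det_primary, dtype=np.int64)
    b = np.asarray(det_secondary, dtype=np.int64)
    if len(a) == 0:
        return np.zeros(0, dtype=bool)
    tol = tol_ms * fs / 1000.0
    matched = np.zeros(len(a), dtype=bool)
    i = j = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= tol:
            matched[i] = True
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    w = halfwidth_s * fs
    lo_a = np.searchsorted(a, a - w)
    hi_a = np.searchsorted(a, a + w)
    lo_b = np.searchsorted(b, a - w)
    hi_b = np.searchsorted(b, a + w)
    cm = np.concatenate([[0], np.cumsum(matched)])
    n_match = cm[hi_a] - cm[lo_a]
    n_a = hi_a - lo_a
    n_b = hi_b - lo_b
    denom = np.maximum(n_a + n_b, 1)
    return (2.0 * n_match / denom) > threshold


def classify_beats(
    signal: np.ndarray,
    fs: float,
    annotations: list[BeatAnnotation],
    context_valid: np.ndarray | None = None,
    wide_qrs_ms: float = WIDE_QRS_MS,
    prematurity_thr: float = PREMATURITY_THR,
    v_corr_thr: float = V_CORR_THR,
    f_corr_thr: float = F_CORR_THR,
) -> list[BeatAnnotation]:
    """Assign each beat one label from {N, S, V, F, none} (in place).

    Rules (deterministic, thresholds configurable):
      none : fiducials absent or local bsqi context invalid;
      V    : QRS > 120 ms AND prematurity < 0.90 AND template corr < 0.8;
      S    : prematurity < 0.90 AND QRS <= 120 ms;
      F    : QRS > 120 ms AND 0.8 <= template corr < 0.95;
      N    : otherwise.

    ``context_valid`` is the optional per-beat mask from
    :func:`local_bsqi_context`.  The template is an exponentially weighted
    mean (alpha=0.05) of beats correlating > 0.9 with it, initialised from
    the medoid of the first 10 delineable beats.  Prematurity is RR_prev
    over the median of the 8 preceding N-labelled RR intervals.
    """
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    w = int(0.15 * fs)
    r = np.array([a.r_sample for a in annotations], dtype=np.int64)

    def beat_window(i: int) -> np.ndarray | None:
        lo, hi = r[i] - w, r[i] + w + 1
        if lo < 0 or hi > n:
            return None
        return signal[lo:hi]

    # template initialisation: medoid of the first 10 usable beats
    init = []
    for i in range(len(annotations)):
        if annotations[i].fiducials:
            bw = beat_window(i)
            if bw is not None:
                init.append(bw)
        if len(init) >= 10:
            break
    template = None
    if init:
        template = BeatTemplate(BeatTemplate._norm(_medoid(np.array(init))))

    recent_nn: list[float] = []
    prev_r_ms: float | None = None
    for i, ann in enumerate(annotations):
        r_ms = r[i] * 1000.0 / fs
        rr_prev = (r_ms - prev_r_ms) if prev_r_ms is not None else float("nan")
        prev_r_ms = r_ms
        if not ann.fiducials or (context_valid is not None
                                 and not context_valid[i]):
            ann.label = "none"
            continue
        bw = beat_window(i)
        corr = template.corr(bw) if (template is not None and bw is not None) else 1.0
        ann.template_corr = corr
        local = statistics.median(recent_nn[-8:]) if recent_nn else float("nan")
        prem = rr_prev / local if (local and np.isfinite(local) and np.isfinite(rr_prev)) else 1.0
        ann.prematurity = prem
        dur = ann.qrs_duration_ms
        wide = np.isfinite(dur) and dur > wide_qrs_ms
        if wide and prem < prematurity_thr and corr < v_corr_thr:
            ann.label = "V"
        elif prem < prematurity_thr and not wide:
            ann.label = "S"
        elif wide and v_corr_thr <= corr < f_corr_thr:
            ann.label = "F"
        else:
            ann.label = "N"
        if ann.label == "N" and np.isfinite(rr_prev):
            recent_nn.append(rr_prev)
        if template is not None and bw is not None and corr > 0.9:
            template.update(bw)
    return annotations
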