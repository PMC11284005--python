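"""Window quality scoring (bsqi) and the exclusion rules.

bsqi is the agreement (F1 score) between two independent QRS detectors run
on the same segment: detections matched one-to-one within a tolerance
count as true positives.  Windows with bsqi <= 0.8 are excluded, windows
overlapping annotated VT events are excluded for C1 recordings (the task
is identification from sinus rhythm), and whole recordings with fewer
than ``min_good_windows`` high-quality windows are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import beats
from .preprocess import EcgRecording, EcgWindow

BSQI_THRESHOLD = 0.8
MIN_GOOD_WINDOWS = 6
MATCH_TOL_MS = 150.0
MIN_WINDOW_S = 10.0


@dataclass
class QualityReport:
    """Per-recording accounting of the quality and VT exclusion rules."""

    recording_id: str
    bsqi_per_window: list = field(default_factory=list)
    quality_threshold: float = BSQI_THRESHOLD
    min_good_windows: int = MIN_GOOD_WINDOWS
    n_windows_total: int = 0
    n_windows_excluded_quality: int = 0
    n_windows_excluded_vt: int = 0
    recording_excluded: bool = False


def bsqi(det_a: np.ndarray, det_b: np.ndarray, tol_ms: float = MATCH_TOL_MS,
         fs: float = 1.0, variant: str = "f1") -> float:
    """Agreement of two detection lists: F1 (default) or Jaccard.

    Greedy earliest-first one-to-one matching of sorted detections within
    +/- ``tol_ms``; TP = matched pairs, FP = unmatched in ``det_b``,
    FN = unmatched in ``det_a``.  Two empty lists agree perfectly (1.0).
    """
    a = np.asarray(det_a, dtype=float)
    b = np.asarray(det_b, dtype=float)
    if np.any(np.diff(a) < 0) or np.any(np.diff(b) < 0):
        raise ValueError("detection lists must be sorted ascending")
    if len(a) == 0 and len(b) == 0:
        return 1.0
    tol = tol_ms * fs / 1000.0
    tp = 0
    i = j = 0
    while i < len(a) and j < len(b):
        if abs(a[i] - b[j]) <= tol:
            tp += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    fn = len(a) - tp
    fp = len(b) - tp
    if variant == "f1":
        return 2.0 * tp / (2.0 * tp + fp + fn)
    if variant == "jaccard":
        return tp / (tp + fp + fn)
    raise ValueError(f"unknown bsqi variant {variant!r}")


def detect_all_leads(recording: EcgRecording):
    """Run both detectors once per lead over the full recording."""
    det_a, det_b = [], []
    for lead in recording.signal:
        try:
            det_a.append(beats.detect_qrs_primary(lead, recording.fs))
            det_b.append(beats.detect_qrs_secondary(lead, recording.fs))
        except ValueError:
            det_a.append(np.array([], dtype=np.int64))
            det_b.append(np.array([], dtype=np.int64))
    return det_a, det_b


def score_windows(windows: list[EcgWindow], recording: EcgRecording,
                  detections=None, tol_ms: float = MATCH_TOL_MS,
                  threshold: float = BSQI_THRESHOLD) -> list[EcgWindow]:
    """Fill each window's bsqi as the best agreement over leads.

    The two detectors run once per lead over the whole recording
    (detections may be passed in to avoid recomputation); each window
    scores the detections falling inside it.  ``lead_used`` is the argmax
    lead — the single lead that feeds all downstream features for that
    window.  Windows shorter than 10 s score 0.
    """
    det_a, det_b = detections if detections is not None else detect_all_leads(recording)
    fs = recording.fs
    for w in windows:
        if (w.end_sample - w.start_sample) / fs < MIN_WINDOW_S:
            w.bsqi, w.quality_ok = 0.0, False
            continue
        best, best_lead = -1.0, 0
        for li in range(recording.n_leads):
            a = det_a[li]
            b = det_b[li]
            a = a[(a >= w.start_sample) & (a < w.end_sample)]
            b = b[(b >= w.start_sample) & (b < w.end_sample)]
            # a lead on which neither detector finds any beat is not
            # assessable, not in perfect agreement
            s = 0.0 if (len(a) == 0 and len(b) == 0) else \
                bsqi(a, b, tol_ms=tol_ms, fs=fs)
            if s > best:
                best, best_lead = s, li
        w.bsqi = best
        w.lead_used = best_lead
        w.quality_ok = best > threshold
    return windows


def apply_exclusions(recording: EcgRecording, windows: list[EcgWindow],
                     threshold: float = BSQI_THRESHOLD,
                     min_good_windows: int = MIN_GOOD_WINDOWS,
                     ) -> tuple[list[EcgWindow], QualityReport]:
    """Apply the window- and recording-level exclusion rules.

    A window is high quality iff bsqi > threshold (a score of exactly 0.8
    is excluded).  C1 windows overlapping an annotated VT event are
    excluded.  If fewer than ``min_good_windows`` windows are high quality,
    the whole recording is excluded and nothing is retained.
    """
    report = QualityReport(
        recording_id=recording.recording_id,
        bsqi_per_window=[w.bsqi for w in windows],
        quality_threshold=threshold,
        min_good_windows=min_good_windows,
        n_windows_total=len(windows),
    )
    good = [w for w in windows if w.bsqi > threshold]
    report.n_windows_excluded_quality = len(windows) - len(good)
    report.recording_excluded = len(good) < min_good_windows
    retained = []
    for w in good:
        if recording.class_label == "C1" and w.contains_vt:
            report.n_windows_excluded_vt += 1
        else:
            retained.append(w)
    if report.recording_excluded:
        return [], report
    return retained, report
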