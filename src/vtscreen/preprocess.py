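"""Recording containers, band-pass/notch filtering, and 30-minute windowing.

The analysis operates on long ambulatory (Holter) ECG recordings.  Each
recording is filtered with a zero-phase second-order IIR band-pass
(0.67--100 Hz) followed by a powerline notch (50 Hz), then cut into
disjoint 30-minute windows that are the unit of feature extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)


@dataclass
class EcgRecording:
    """A multi-lead sampled ECG with metadata.

    ``signal`` has shape (n_leads, n_samples), in millivolts.
    ``vt_events`` is a list of half-open sample intervals covering annotated
    ventricular-tachycardia episodes (possibly empty).
    """

    patient_id: str
    recording_id: str
    signal: np.ndarray
    fs: float
    class_label: str = "C0"
    pi: dict = field(default_factory=dict)
    vt_events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        n = self.signal.shape[1]
        for lo, hi in self.vt_events:
            if not (0 <= lo <= hi <= n):
                raise ValueError("vt_events must lie within the signal")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class FilterSpec:
    """Band-pass + notch configuration (defaults follow the study protocol)."""

    passband_low: float = 0.67
    passband_high: float = 100.0
    order: int = 2
    notch_freq: float = 50.0
    notch_q: float = 30.0


@dataclass
class EcgWindow:
    """A 30-min slice of one recording; quality fields filled later."""

    recording_id: str
    window_index: int
    start_sample: int
    end_sample: int
    duration_min: float = 30.0
    lead_used: int | None = None
    bsqi: float = float("nan")
    quality_ok: bool | None = None
    contains_vt: bool = False


def apply_filters(recording: EcgRecording, spec: FilterSpec | None = None) -> EcgRecording:
    """Zero-phase band-pass then notch filtering, per lead.

    The band-pass is a single second-order section run forward-backward
    (``sosfiltfilt``), so the effective order doubles and the phase is zero.
    ``passband_high`` is clipped to 0.45*fs when it would exceed Nyquist
    (low sampling rates); the notch is skipped when fs <= 2*notch_freq.
    """
    spec = spec or FilterSpec()
    fs = recording.fs
    low = spec.passband_low
    high = spec.passband_high
    if fs <= 2.0 * low:
        raise ValueError(f"fs={fs} too low for passband_low={low}")
    if high >= 0.5 * fs:
        high = 0.45 * fs
        logger.warning("passband_high clipped to %.3g Hz (fs=%.3g)", high, fs)
    sos = sps.butter(spec.order, [low, high], btype="bandpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, recording.signal, axis=1)
    if fs > 2.0 * spec.notch_freq:
        b, a = sps.iirnotch(spec.notch_freq, spec.notch_q, fs=fs)
        out = sps.filtfilt(b, a, out, axis=1)
    else:
        logger.warning("notch at %.3g Hz skipped (fs=%.3g)", spec.notch_freq, fs)
    return replace(recording, signal=out)


def split_windows(recording: EcgRecording, duration_min: float = 30.0) -> list[EcgWindow]:
    """Cut a recording into maximal disjoint full windows from sample 0.

    The trailing partial window is discarded so every window has identical
    length (feature comparability).  ``contains_vt`` is set by overlap with
    the recording's annotated VT intervals.
    """
    wlen = int(round(duration_min * 60.0 * recording.fs))
    n = recording.n_samples
    if n < wlen:
        logger.warning("recording %s shorter than one window", recording.recording_id)
        return []
    windows = []
    for k in range(n // wlen):
        lo, hi = k * wlen, (k + 1) * wlen
        has_vt = any(ev_lo < hi and ev_hi > lo for ev_lo, ev_hi in recording.vt_events)
        windows.append(
            EcgWindow(
                recording_id=recording.recording_id,
                window_index=k,
                start_sample=lo,
                end_sample=hi,
                duration_min=duration_min,
                contains_vt=has_vt,
            )
        )
    return windows
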