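"""Recording and annotation I/O: WFDB (format 16) and CSV.

A self-contained reader/writer for the WFDB subset this package needs:
``.hea`` headers, interleaved 16-bit little-endian ``.dat`` signals, and
MIT-format annotation files (beat codes N, S, V, F, Q plus rhythm labels
with aux strings).  Patient metadata travels in header comment lines as
JSON; CSV recordings (columns time_s, lead1..leadK) carry it in a JSON
sidecar instead.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .beats import BeatAnnotation
from .preprocess import EcgRecording

ADC_GAIN = 200.0  # ADC units per mV
_FMT = 16

#: MIT annotation codes for the 5-class label set ("none" -> Q, unclassifiable)
BEAT_CODE = {"N": 1, "V": 5, "F": 6, "S": 8, "none": 13}
CODE_BEAT = {v: k for k, v in BEAT_CODE.items()}
_RHYTHM = 28
_AUX = 63
_SKIP = 59


# ---------------------------------------------------------------------------
# WFDB signals
# ---------------------------------------------------------------------------

def write_wfdb(recording: EcgRecording, directory, name: str | None = None) -> Path:
    """Write ``name.hea`` + ``name.dat`` (format 16); returns the header path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or recording.recording_id
    sig = recording.signal
    adc = np.clip(np.round(sig * ADC_GAIN), -32768, 32767).astype("<i2")
    inter = adc.T.reshape(-1)
    (directory / f"{name}.dat").write_bytes(inter.tobytes())
    checksums = [int(np.sum(adc[i], dtype=np.int16)) for i in range(adc.shape[0])]
    lines = [f"{name} {sig.shape[0]} {recording.fs:g} {sig.shape[1]}"]
    for i in range(sig.shape[0]):
        lines.append(
            f"{name}.dat {_FMT} {ADC_GAIN:g}(0)/mV 16 0 {int(adc[i, 0])} "
            f"{checksums[i]} 0 lead{i + 1}"
        )
    meta = {
        "patient_id": recording.patient_id,
        "recording_id": recording.recording_id,
        "class_label": recording.class_label,
        "pi": recording.pi,
        "vt_events": [[int(a), int(b)] for a, b in recording.vt_events],
    }
    lines.append("# " + json.dumps(meta))
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    return directory / f"{name}.hea"


def read_wfdb(header_path) -> EcgRecording:
    """Read a format-16 WFDB record written by :func:`write_wfdb`."""
    header_path = Path(header_path)
    if header_path.suffix != ".hea":
        header_path = header_path.with_suffix(".hea")
    lines = [ln for ln in header_path.read_text().splitlines() if ln.strip()]
    meta = {}
    for ln in lines:
        if ln.startswith("# {"):
            meta = json.loads(ln[2:])
    head = lines[0].split()
    name, nsig, fs, nsamp = head[0], int(head[1]), float(head[2]), int(head[3])
    gains = []
    for ln in lines[1:nsig + 1]:
        parts = ln.split()
        if int(parts[1]) != _FMT:
            raise ValueError(f"unsupported WFDB format {parts[1]}")
        gains.append(float(parts[2].split("(")[0]))
    raw = np.frombuffer((header_path.parent / f"{name}.dat").read_bytes(),
                        dtype="<i2")
    sig = raw.reshape(nsamp, nsig).T.astype(float)
    sig /= np.array(gains)[:, None]
    return EcgRecording(
        patient_id=meta.get("patient_id", name),
        recording_id=meta.get("recording_id", name),
        signal=sig,
        fs=fs,
        class_label=meta.get("class_label", "C0"),
        pi=meta.get("pi", {}),
        vt_events=[tuple(ev) for ev in meta.get("vt_events", [])],
    )


# ---------------------------------------------------------------------------
# WFDB annotations (MIT format)
# ---------------------------------------------------------------------------

def write_annotations(path, annotations: list[BeatAnnotation],
                      rhythm_events: list | None = None) -> Path:
    """Write beats (and optional VT rhythm intervals) as an MIT .atr file.

    Rhythm events are (start_sample, end_sample) pairs emitted as RHYTHM
    annotations with aux strings ``(VT`` and ``(N``.
    """
    events = [(a.r_sample, BEAT_CODE.get(a.label, 13), None) for a in annotations]
    for lo, hi in rhythm_events or []:
        events.append((int(lo), _RHYTHM, "(VT"))
        events.append((int(hi), _RHYTHM, "(N"))
    events.sort(key=lambda e: e[0])
    buf = bytearray()
    prev = 0
    for sample, code, aux in events:
        delta = sample - prev
        prev = sample
        if delta >= 1024 or delta < 0:
            buf += int(_SKIP << 10).to_bytes(2, "little")
            buf += ((delta >> 16) & 0xFFFF).to_bytes(2, "little")
            buf += (delta & 0xFFFF).to_bytes(2, "little")
            delta = 0
        buf += ((code << 10) | (delta & 0x3FF)).to_bytes(2, "little")
        if aux:
            raw = aux.encode()
            buf += ((_AUX << 10) | len(raw)).to_bytes(2, "little")
            buf += raw
            if len(raw) % 2:
                buf += b"\x00"
    buf += b"\x00\x00"
    path = Path(path)
    path.write_bytes(bytes(buf))
    return path


def read_annotations(path) -> tuple[list[BeatAnnotation], list]:
    """Read an MIT .atr file back into beats + VT rhythm intervals."""
    data = Path(path).read_bytes()
    beats_out: list[BeatAnnotation] = []
    vt_runs: list = []
    open_vt: int | None = None
    sample = 0
    pending_skip = 0
    i = 0
    while i + 1 < len(data):
        word = int.from_bytes(data[i:i + 2], "little")
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if code == 0 and delta == 0:
            break
        if code == _SKIP:
            hi = int.from_bytes(data[i:i + 2], "little")
            lo = int.from_bytes(data[i + 2:i + 4], "little")
            i += 4
            pending_skip = (hi << 16) | lo
            continue
        if code == _AUX:
            aux = data[i:i + delta].decode()
            i += delta + (delta % 2)
            if aux == "(VT":
                open_vt = sample
            elif aux == "(N" and open_vt is not None:
                vt_runs.append((open_vt, sample))
                open_vt = None
            continue
        sample += delta + pending_skip
        pending_skip = 0
        if code in CODE_BEAT:
            beats_out.append(BeatAnnotation(r_sample=sample, label=CODE_BEAT[code]))
    return beats_out, vt_runs


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def write_csv(recording: EcgRecording, directory, name: str | None = None) -> Path:
    """Write ``name.csv`` (time_s, lead1..leadK) + JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or recording.recording_id
    t = np.arange(recording.n_samples) / recording.fs
    df = pd.DataFrame({"time_s": t})
    for i in range(recording.n_leads):
        df[f"lead{i + 1}"] = recording.signal[i]
    path = directory / f"{name}.csv"
    df.to_csv(path, index=False, float_format="%.5f")
    meta = {
        "fs": recording.fs,
        "patient_id": recording.patient_id,
        "recording_id": recording.recording_id,
        "class_label": recording.class_label,
        "pi": recording.pi,
        "vt_events": [[int(a), int(b)] for a, b in recording.vt_events],
    }
    (directory / f"{name}.json").write_text(json.dumps(meta, indent=1))
    return path


def read_csv(path) -> EcgRecording:
    """Read a CSV recording; fs comes from the sidecar or the time column."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if "fs" in meta:
        fs = float(meta["fs"])
    elif "time_s" in df.columns and len(df) > 1:
        fs = 1.0 / float(np.mean(np.diff(df["time_s"].to_numpy()[:1000])))
    else:
        raise ValueError("cannot determine sampling frequency: no sidecar fs "
                         "and no time_s column")
    leads = [c for c in df.columns if c.startswith("lead")]
    if not leads:
        raise ValueError("no lead columns found")
    sig = df[leads].to_numpy().T
    return EcgRecording(
        patient_id=meta.get("patient_id", path.stem),
        recording_id=meta.get("recording_id", path.stem),
        signal=sig,
        fs=fs,
        class_label=meta.get("class_label", "C0"),
        pi=meta.get("pi", {}),
        vt_events=[tuple(ev) for ev in meta.get("vt_events", [])],
    )


def load_recording(path, format: str | None = None) -> EcgRecording:
    """Load a recording, inferring the format from the extension if needed."""
    path = Path(path)
    fmt = format or {".hea": "wfdb", ".dat": "wfdb", ".csv": "csv"}.get(path.suffix)
    if fmt == "wfdb":
        return read_wfdb(path)
    if fmt == "csv":
        return read_csv(path)
    raise ValueError(f"unknown recording format for {path}")
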