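"""Synthetic Holter cohort generator with full ground truth.

Emulates the statistical structure the downstream analysis assumes: a
labelled two-class cohort (C0 = non-VT, C1 = VT patients) of multi-hour,
multi-lead ECG recordings with class-dependent premature-ventricular-
contraction (PVC) burden, tunable RR fragmentation, sum-of-Gaussians beat
morphology, noise episodes that produce low-quality windows, and optional
ventricular-tachycardia runs in C1 recordings.

The RR process is mean heart rate plus a stationary disturbance whose
increments follow an AR(1) law with coefficient ``frag_coeff`` (the lag-1
autocorrelation of RR increments): negative values produce the frequent
acceleration/deceleration reversals that fragmentation metrics (PIP, IALS,
PSS, PAS) quantify.  Each PVC shortens its own interval to a coupling
fraction of the running RR and is followed by a full compensatory pause
(the pair sums to twice the local mean RR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import BeatAnnotation
from .preprocess import EcgRecording

RR_CLIP_MS = (300.0, 2500.0)

#: per-lead gains for the default 3-lead rendering (scaled copies)
LEAD_GAINS = (1.0, 0.7, 0.85)

# beat morphology: (center ms, sigma ms, amplitude) -- amplitudes relative to
# r_amp.  Normal-beat QRS spans ~80 ms between 3-sigma bounds of Q and S.
N_BUMPS = {
    "P": (-160.0, 22.0, 0.12),
    "Q": (-20.0, 6.7, -0.08),
    "R": (0.0, 10.0, 1.0),
    "S": (20.0, 6.7, -0.20),
    "T": (300.0, 60.0, 0.30),
}
# V beats: no P, widths scaled by pvc_width_factor, deep late inverted S and
# inverted T -- a wide bizarre complex clearly distinct from the template.
V_BUMPS = {
    "Q": (-20.0, 6.7, -0.10),
    "R": (0.0, 10.0, 0.85),
    "S": (22.0, 8.0, 0.55),
    "T": (320.0, 70.0, -0.30),
}


@dataclass
class PatientProfile:
    """Generative parameters of one synthetic patient."""

    patient_id: str
    class_label: str
    age: float
    sex: str
    bmi: float
    smoking: bool
    mean_hr: float
    rr_sd: float
    frag_coeff: float
    lf_amp: float
    hf_amp: float
    pvc_prob: float
    pvc_coupling: float
    r_amp: float
    pvc_width_factor: float
    noise_level: float
    n_bad_segments: int

    def __post_init__(self) -> None:
        if not 30.0 <= self.mean_hr <= 180.0:
            raise ValueError("mean_hr must lie in [30, 180] b.p.m.")
        if not -0.95 <= self.frag_coeff <= 0.95:
            raise ValueError("frag_coeff must lie in [-0.95, 0.95]")
        if not 0.0 <= self.pvc_prob <= 0.3:
            raise ValueError("pvc_prob must lie in [0, 0.3]")

    @property
    def mean_rr_ms(self) -> float:
        return 60000.0 / self.mean_hr


@dataclass
class ParamDist:
    """Class-conditional truncated-normal parameter distribution.

    C1 draws use ``mean_c0 + shift_mean`` and ``sd_c0 + shift_sd``; both
    shifts are multiplied by the cohort's ``effect_size_scale``, so a scale
    of zero makes the two class distributions identical.
    """

    mean_c0: float
    sd_c0: float
    shift_mean: float = 0.0
    shift_sd: float = 0.0
    low: float = -np.inf
    high: float = np.inf

    def draw(self, rng: np.random.Generator, is_c1: bool, scale: float) -> float:
        mean = self.mean_c0 + (self.shift_mean * scale if is_c1 else 0.0)
        sd = self.sd_c0 + (self.shift_sd * scale if is_c1 else 0.0)
        if sd < 0:
            raise ValueError("negative standard deviation in parameter distribution")
        return float(np.clip(rng.normal(mean, sd), self.low, self.high))


def default_param_dists() -> dict:
    """Default class-conditional distributions for every profile field.

    C1 patients carry a higher PVC burden (mean per-beat probability 0.05
    vs 0.005) and a fragmentation coefficient shifted by -0.35; the four
    patient-information fields are deliberately identical across classes so
    a PI-only classifier has nothing to learn.
    """
    return {
        "mean_hr": ParamDist(75.0, 10.0, low=45.0, high=110.0),
        "rr_sd": ParamDist(40.0, 12.0, shift_mean=5.0, low=5.0, high=120.0),
        "frag_coeff": ParamDist(0.25, 0.20, shift_mean=-0.35, shift_sd=0.05,
                                low=-0.9, high=0.9),
        "lf_amp": ParamDist(18.0, 6.0, low=0.0, high=50.0),
        "hf_amp": ParamDist(12.0, 5.0, low=0.0, high=50.0),
        "pvc_prob": ParamDist(0.005, 0.004, shift_mean=0.045, shift_sd=0.026,
                              low=0.0, high=0.3),
        "pvc_coupling": ParamDist(0.60, 0.07, low=0.35, high=0.85),
        "r_amp": ParamDist(1.1, 0.2, low=0.4, high=2.5),
        "pvc_width_factor": ParamDist(2.0, 0.15, shift_mean=0.1, low=1.6, high=3.0),
        "noise_level": ParamDist(0.03, 0.012, low=0.005, high=0.15),
        "age": ParamDist(62.0, 14.0, low=18.0, high=95.0),
        "bmi": ParamDist(27.0, 4.0, low=16.0, high=45.0),
    }


@dataclass
class CohortSpec:
    """Cohort-level configuration: counts, duration, class effect sizes."""

    n_c0: int = 160
    n_c1: int = 40
    recordings_per_patient: int = 1
    duration_h: float = 1.0
    fs: float = 128.0
    params: dict = field(default_factory=default_param_dists)
    effect_size_scale: float = 1.0
    sex_p_male: float = 0.55
    smoking_p: float = 0.30
    bad_segment_rate: float = 0.5
    #: probability that a C1 recording contains annotated VT runs
    vt_run_prob: float = 0.6
    seed: int = 0


@dataclass
class GroundTruth:
    """Exact generative record of one recording."""

    rr_series: np.ndarray          # ms, interval k ends at beat k
    beat_times: np.ndarray         # seconds from recording start
    beat_labels: np.ndarray        # {'N','S','V','F'} per beat
    vt_runs: list = field(default_factory=list)   # (start_sample, end_sample)
    duration_s: float = 0.0

    @property
    def realized_pvc_fraction(self) -> float:
        if len(self.beat_labels) == 0:
            return 0.0
        return float(np.mean(self.beat_labels == "V"))


def sample_cohort(spec: CohortSpec) -> list[PatientProfile]:
    """Draw ``n_c0 + n_c1`` patient profiles, deterministically from the seed."""
    if spec.n_c0 < 0 or spec.n_c1 < 0:
        raise ValueError("patient counts must be non-negative")
    rng = np.random.default_rng(spec.seed)
    profiles = []
    labels = ["C0"] * spec.n_c0 + ["C1"] * spec.n_c1
    for i, lab in enumerate(labels):
        is_c1 = lab == "C1"
        draws = {k: d.draw(rng, is_c1, spec.effect_size_scale)
                 for k, d in spec.params.items()}
        profiles.append(
            PatientProfile(
                patient_id=f"pat{i:04d}",
                class_label=lab,
                age=draws["age"],
                sex="M" if rng.random() < spec.sex_p_male else "F",
                bmi=draws["bmi"],
                smoking=bool(rng.random() < spec.smoking_p),
                mean_hr=draws["mean_hr"],
                rr_sd=draws["rr_sd"],
                frag_coeff=draws["frag_coeff"],
                lf_amp=draws["lf_amp"],
                hf_amp=draws["hf_amp"],
                pvc_prob=draws["pvc_prob"],
                pvc_coupling=draws["pvc_coupling"],
                r_amp=draws["r_amp"],
                pvc_width_factor=draws["pvc_width_factor"],
                noise_level=draws["noise_level"],
                n_bad_segments=int(rng.poisson(spec.bad_segment_rate)),
            )
        )
    return profiles


def generate_rr_series(profile: PatientProfile, duration_h: float,
                       seed: int | np.random.Generator = 0) -> GroundTruth:
    """Generate the RR interval series and beat labels (no waveform).

    Base RR = mean RR + a stationary disturbance whose increments are AR(1)
    with coefficient ``frag_coeff``, plus sinusoidal LF (0.1 Hz) and HF
    (0.25 Hz) modulation.  Each beat independently becomes a PVC (drawn so
    the realized V fraction converges to ``pvc_prob``); a PVC shortens its
    own interval to ``pvc_coupling`` x the running RR and the next interval
    completes a full compensatory pause.  RR is clipped to [300, 2500] ms.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration_ms = duration_h * 3600.0 * 1000.0
    mean_rr = profile.mean_rr_ms
    n_max = int(duration_ms / mean_rr * 1.6) + 64

    if profile.rr_sd > 0:
        from scipy.signal import lfilter

        e = rng.standard_normal(n_max)
        d = lfilter([1.0], [1.0, -profile.frag_coeff], e)
        # leaky integration keeps the level stationary while preserving the
        # increment autocorrelation (increments ~ d for decay near 1)
        z = lfilter([1.0], [1.0, -0.95], d)
        z *= profile.rr_sd / max(np.std(z), 1e-12)
    else:
        z = np.zeros(n_max)

    t_approx = np.arange(n_max) * mean_rr / 1000.0
    rr = (mean_rr + z
          + profile.lf_amp * np.sin(2 * np.pi * 0.1 * t_approx)
          + profile.hf_amp * np.sin(2 * np.pi * 0.25 * t_approx))
    rr = np.clip(rr, *RR_CLIP_MS)

    labels = np.full(n_max, "N", dtype="<U4")
    # draw probability chosen so the stationary V fraction equals pvc_prob
    # (a PVC occupies the slot after it as its compensatory pause)
    p_draw = min(1.0, profile.pvc_prob / max(1.0 - profile.pvc_prob, 1e-9))
    u = rng.random(n_max)
    i = 1
    while i < n_max - 1:
        if u[i] < p_draw and labels[i - 1] != "V":
            local = float(np.mean(rr[max(0, i - 5):i + 1]))
            rr[i] = profile.pvc_coupling * rr[i]
            rr[i + 1] = 2.0 * local - rr[i]
            labels[i] = "V"
            i += 2
        else:
            i += 1
    rr = np.clip(rr, *RR_CLIP_MS)

    t = np.cumsum(rr) / 1000.0
    keep = t <= duration_h * 3600.0
    return GroundTruth(
        rr_series=rr[keep],
        beat_times=t[keep],
        beat_labels=labels[keep],
        duration_s=duration_h * 3600.0,
    )


def _render_clean(gt: GroundTruth, profile: PatientProfile, fs: float,
                  n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Sum-of-Gaussians rendering of all beats onto one clean lead."""
    sig = np.zeros(n_samples)
    amp_jit = rng.normal(1.0, 0.05, size=len(gt.beat_times))
    for label_sel, bumps, widen in (
        (gt.beat_labels != "V", N_BUMPS, 1.0),
        (gt.beat_labels == "V", V_BUMPS, profile.pvc_width_factor),
    ):
        times = gt.beat_times[label_sel]
        jit = amp_jit[label_sel]
        if len(times) == 0:
            continue
        for name, (c_ms, s_ms, amp) in bumps.items():
            w = widen if name in ("Q", "R", "S") else max(1.0, 0.5 * widen)
            c_s, sigma = (c_ms * w) / 1000.0, (s_ms * w) / 1000.0
            halfw = int(np.ceil(4 * sigma * fs))
            rel = np.arange(-halfw, halfw + 1)
            centers = times + c_s
            idx = np.round(centers * fs).astype(np.int64)[:, None] + rel[None, :]
            tdev = idx / fs - centers[:, None]
            vals = (amp * profile.r_amp * jit[:, None]
                    * np.exp(-0.5 * (tdev / sigma) ** 2))
            ok = (idx >= 0) & (idx < n_samples)
            np.add.at(sig, idx[ok], vals[ok])
    return sig


def synthesize_ecg(gt: GroundTruth, profile: PatientProfile, fs: float,
                   seed: int | np.random.Generator = 0,
                   lead_gains: tuple = LEAD_GAINS,
                   recording_id: str = "rec0",
                   ) -> tuple[EcgRecording, list[BeatAnnotation]]:
    """Render the ground truth as a multi-lead sampled ECG.

    Each beat is a sum of five Gaussian bumps (P, Q, R, S, T); V beats have
    no P bump, QRS widths multiplied by ``pvc_width_factor``, and inverted
    late-QRS/T polarity so their QRS exceeds the 120 ms wide-complex bound.
    Leads are scaled copies of one source waveform with independent noise:
    baseline wander (0.25 Hz), white noise at ``noise_level`` RMS, 50 Hz
    powerline, plus ``n_bad_segments`` episodes of x20 noise.
    """
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz to render QRS complexes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = int(round(gt.duration_s * fs))
    clean = _render_clean(gt, profile, fs, n_samples, rng)

    t = np.arange(n_samples) / fs
    episodes = []
    for _ in range(profile.n_bad_segments):
        length = rng.uniform(60.0, 300.0)
        start = rng.uniform(0.0, max(0.0, gt.duration_s - length))
        episodes.append((int(start * fs), int((start + length) * fs)))

    leads = np.empty((len(lead_gains), n_samples))
    burst_rms = 20.0 * max(profile.noise_level, 0.01)
    for li, g in enumerate(lead_gains):
        noise = rng.normal(0.0, profile.noise_level, n_samples)
        noise += 0.10 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
        noise += 0.02 * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        for lo, hi in episodes:
            noise[lo:hi] += rng.normal(0.0, burst_rms, hi - lo)
        leads[li] = g * clean + noise

    rec = EcgRecording(
        patient_id=profile.patient_id,
        recording_id=recording_id,
        signal=leads,
        fs=fs,
        class_label=profile.class_label,
        pi={"age": profile.age, "sex": profile.sex,
            "bmi": profile.bmi, "smoking": profile.smoking},
        vt_events=list(gt.vt_runs),
    )
    anns = [
        BeatAnnotation(r_sample=int(round(bt * fs)), label=str(lab))
        for bt, lab in zip(gt.beat_times, gt.beat_labels)
        if 0 <= int(round(bt * fs)) < n_samples
    ]
    return rec, anns


def inject_vt_runs(gt: GroundTruth, profile: PatientProfile, fs: float,
                   n_runs: int, run_length_beats: int = 5,
                   run_rate_bpm: float = 150.0,
                   seed: int | np.random.Generator = 0,
                   recording_id: str = "rec0",
                   ) -> tuple[EcgRecording, GroundTruth]:
    """Insert VT runs (consecutive V beats at >100 b.p.m.) and re-render.

    Picks ``n_runs`` non-overlapping beat positions, rewrites the intervals
    of ``run_length_beats`` consecutive beats to 60000/rate ms, labels them
    V, recomputes beat times, updates ``vt_runs`` (sample intervals spanning
    first to last run beat), and synthesizes the modified recording.
    """
    if n_runs < 0:
        raise ValueError("n_runs must be non-negative")
    if n_runs > 0 and run_length_beats < 3:
        raise ValueError("a VT run needs at least 3 beats")
    if n_runs > 0 and run_rate_bpm <= 100:
        raise ValueError("VT rate must exceed 100 b.p.m.")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rr = gt.rr_series.copy()
    labels = gt.beat_labels.copy()
    n = len(rr)
    if n_runs > 0 and n_runs * (run_length_beats + 10) > n - 10:
        raise ValueError("requested VT runs exceed recording length")

    run_spans = []
    if n_runs > 0:
        vt_rr = 60000.0 / run_rate_bpm
        taken: list[tuple[int, int]] = []
        tries = 0
        while len(taken) < n_runs and tries < 1000:
            tries += 1
            s = int(rng.integers(5, n - run_length_beats - 5))
            if all(s + run_length_beats + 2 < a or s > b + 2 for a, b in taken):
                taken.append((s, s + run_length_beats - 1))
        for s, e in sorted(taken):
            rr[s:e + 1] = vt_rr
            labels[s:e + 1] = "V"
        t = np.cumsum(rr) / 1000.0
        keep = t <= gt.duration_s
        rr, labels, t = rr[keep], labels[keep], t[keep]
        for s, e in sorted(taken):
            if e < len(t):
                run_spans.append((int(t[s] * fs), int(t[e] * fs) + 1))
    else:
        t = gt.beat_times.copy()

    new_gt = GroundTruth(rr_series=rr, beat_times=t, beat_labels=labels,
                         vt_runs=list(gt.vt_runs) + run_spans,
                         duration_s=gt.duration_s)
    rec, _ = synthesize_ecg(new_gt, profile, fs, seed=rng,
                            recording_id=recording_id)
    return rec, new_gt


def simulate_recording(profile: PatientProfile, spec: CohortSpec,
                       rng: np.random.Generator, recording_id: str,
                       ) -> tuple[EcgRecording, GroundTruth]:
    """One recording for one patient: RR process, optional VT runs, waveform."""
    gt = generate_rr_series(profile, spec.duration_h, rng)
    if profile.class_label == "C1" and rng.random() < spec.vt_run_prob:
        n_runs = int(rng.integers(1, 3))
        length = int(rng.integers(3, 11))
        rate = float(rng.uniform(130.0, 190.0))
        try:
            return inject_vt_runs(gt, profile, spec.fs, n_runs, length, rate,
                                  seed=rng, recording_id=recording_id)
        except ValueError:
            pass
    rec, _ = synthesize_ecg(gt, profile, spec.fs, seed=rng,
                            recording_id=recording_id)
    return rec, gt


def simulate_cohort(spec: CohortSpec):
    """Yield (profile, recording, ground truth) for the whole cohort."""
    profiles = sample_cohort(spec)
    root = np.random.SeedSequence(spec.seed)
    for profile, child in zip(profiles, root.spawn(len(profiles))):
        rng = np.random.default_rng(child)
        for k in range(spec.recordings_per_patient):
            rec_id = f"{profile.patient_id}_r{k}"
            rec, gt = simulate_recording(profile, spec, rng, rec_id)
            yield profile, rec, gt
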