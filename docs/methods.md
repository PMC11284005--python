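# Methods

This note documents the models, defaults, numerical choices, and
limitations of the `vtscreen` pipeline and its synthetic cohort
generator.

## The task and its structure

The pipeline classifies a *patient* (not an episode) as VT-prone or not,
using only sinus-rhythm ECG.  Windows are the unit of feature
extraction and model training; patients are the unit of evaluation.
Three ingredients protect that structure: windows overlapping annotated
VT events are excluded from the positive class, train/test splits and
inner CV folds are partitioned by patient, and per-window probabilities
are aggregated to a patient score by the median.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with full ground truth; it does not attempt physiological realism beyond
what the features can see.

**RR process.** Base RR = 60000/HR ms plus a stationary disturbance:
white innovations pass through an AR(1) filter with coefficient
`frag_coeff` and then a leaky integrator (decay 0.95), so the *increments*
of the disturbance inherit lag-1 autocorrelation ≈ `frag_coeff` while the
level stays bounded; the disturbance is rescaled to `rr_sd`.  Negative
`frag_coeff` produces frequent acceleration/deceleration reversals —
exactly what the fragmentation metrics measure: the probability of a sign
change between consecutive Gaussian AR(1) increments is arccos(φ)/π, so
PIP falls monotonically as φ rises (≈0.79 at φ=−0.8, 0.50 at 0, 0.22 at
+0.8, matching simulation).  Sinusoidal LF (0.1 Hz) and HF (0.25 Hz)
modulation with per-patient amplitudes feeds the spectral features.  RR
is clipped to [300, 2500] ms.

**Ectopy.** Each beat independently becomes a PVC with a probability
chosen so the realized V fraction converges to the profile's `pvc_prob`
(a PVC occupies the following slot with its compensatory pause, so the
raw draw probability is p/(1−p)).  A PVC shortens its own interval to
`pvc_coupling` × the running RR; the next interval completes a full
compensatory pause (the pair sums to twice the local mean RR, the classic
ventricular-ectopy signature that makes prematurity rules work).
Consecutive PVCs are not generated; VT runs are inserted explicitly by
`inject_vt_runs` (≥3 consecutive V beats at >100 b.p.m.).

**Waveform.** Each beat is a sum of five Gaussian bumps (P, Q, R, S, T).
Normal QRS spans ~80 ms between the 3σ bounds of Q and S.  V beats carry
no P bump, QRS widths multiplied by `pvc_width_factor` (default 2, QRS
>120 ms as rendered), a slightly lower R amplitude, and inverted late-QRS
and T polarity — wide, bizarre, and morphologically distinct from the
running template, as real PVCs are.  Leads are scaled copies (gains 1.0 /
0.7 / 0.85) of one source waveform with independent noise: baseline
wander (0.25 Hz, 0.1 mV), white noise at the profile's `noise_level`
(default ~0.03 mV RMS), 50 Hz powerline (0.02 mV), and `n_bad_segments`
episodes of ×20 noise lasting 60–300 s — these create windows that fail
the quality gate without sinking whole recordings.

**Class effects (defaults).** C1 patients draw `pvc_prob` from
N(0.05, 0.03) vs N(0.005, 0.004) for C0 (clipped to [0, 0.3]) and
`frag_coeff` shifted by −0.35.  The demographic fields (age, sex, BMI,
smoking) are *identical across classes by design*, so a
demographics-only model has nothing to learn — the expected outcome for
that variant is chance.  `effect_size_scale` multiplies every C1–C0 shift;
zero makes the classes statistically identical (the null cohort used for
calibration checks).  There is no published quantitative PVC-burden
distribution for this contrast; these defaults are stated assumptions
chosen to make the default cohort separable but not trivially so, and are
fully configurable.

**What the generator does not emulate**, hence what passing tests do not
show: atrial fibrillation and other confounding rhythms (a documented
source of false positives in real cohorts), respiration-coupled
morphology, electrode placement variability, multi-lead vector
physiology, pacemaker artefacts.  Results on this cohort demonstrate the
pipeline's internal correctness and sensitivity to the encoded effects,
not clinical performance.

## Signal processing choices

- Band-pass: one second-order Butterworth section 0.67–100 Hz applied
  forward–backward (zero phase; effective order doubles).  The upper edge
  is clipped to 0.45·fs when fs < 200 Hz, since 100 Hz exceeds Nyquist at
  Holter rates.  Notch: second-order IIR at 50 Hz, Q = 30, skipped with a
  warning when fs ≤ 100 Hz.
- Windows are full 30-min blocks from sample 0; the trailing partial
  window is discarded so all windows are identically sized.
- bsqi = F1 of greedy one-to-one matching of the two detectors'
  outputs within ±150 ms (the conventional inter-detector agreement
  window; configurable, Jaccard variant available).  For sorted point
  sets with a symmetric tolerance the two-pointer greedy attains the
  maximum matching cardinality — asserted against a brute-force
  maximum bipartite matching in the tests.  A window scores the best
  lead; that lead feeds all of the window's features.  A bsqi of exactly
  0.8 is *excluded* (the high-quality rule is strict >).
- The two detectors fail differently by construction: the energy
  detector's adaptive threshold keeps firing on broadband noise, while
  the curve-length detector's fixed order-statistic threshold
  (max(2 × median, 0.25 × p95) of the transform) goes nearly silent,
  because the curve-length transform of noise concentrates near its
  median.  Their disagreement is what makes bsqi drop on noise.
- Delineation runs on a 20 ms moving average (nulls 50 Hz residue,
  leaves σ≈10 ms QRS flanks nearly intact).  QRS on/offset: from the
  maximal up/down-slope flank outward until |derivative| stays below
  max(5% of peak slope, 2.5 × the 25th percentile of |derivative| in the
  segment) for two consecutive samples — the run requirement skips the
  zero-slope instants at Q/S troughs; the floor keeps residual noise from
  stranding the search.  T-end by the tangent method in the 80–400 ms
  post-QRS window; P as the largest positive smoothed bump ≥0.05 mV in
  the 200 ms pre-QRS window, required to peak strictly inside the window
  (a neighbouring wave's tail peaks at the boundary) and to start after
  the previous T-end plus 60 ms.  `Tdur` is defined as 2·(T_end − T_peak)
  because no T-onset fiducial is delineated.
- R times for HRV are refined to sub-sample precision by parabolic
  interpolation through the three samples at the peak: at 128 Hz the
  ±half-sample quantization (≈2.3 ms SD) is comparable to small RR
  increments and would otherwise blur the fragmentation metrics; the
  refinement reduces jitter to ≈0.4 ms.

## Beat classification

The five-class labelling is a deterministic rule set over three
quantities — QRS duration, prematurity (RR_prev over the median of the
8 preceding N-labelled intervals), and Pearson correlation with a
running unit-energy template (exponentially weighted mean, α = 0.05, of
beats correlating >0.9, initialised from the medoid of the first 10
delineable beats):

- none: fiducials absent, or the local bsqi context is invalid — the
  inter-detector F1 in a ±5 s neighbourhood of the beat is ≤0.8,
  catching noise bursts shorter than a window;
- V: wide (>120 ms) and premature (<0.90) and morphologically novel
  (corr <0.8);
- S: premature but narrow;
- F: wide with intermediate correlation (0.8–0.95);
- N: otherwise.

All thresholds are configurable.  This stand-in replaces a published
clustering-based classifier that is used as a black box upstream; the
rule set keeps the pipeline self-contained and testable.  On the default
synthetic cohort it reaches V sensitivity ≈1.0 and specificity ≈1.0 on
clean signal, and the per-window detected V fraction regresses on the
generator's true PVC fraction with slope ≈1 and r > 0.95.

## Features

All valid RR intervals (300–2500 ms) enter the HRV computations,
including intervals around ectopic beats: PVC-induced irregularity is
part of the class signal, not an artefact.  pNNx uses strict inequality.
Fragmentation treats a zero increment as a sign change; run membership
is counted over increments and fractions are relative to the number of
increments (under this convention PIP of a perfect alternation of n
intervals is (n−2)/n and PAS is 1, exactly).  Spectral powers come from
a Lomb–Scargle periodogram of the unevenly sampled NN series (no
resampling), scaled to a one-sided PSD in ms²/Hz, integrated over VLF
0.0033–0.04 / LF 0.04–0.15 / HF 0.15–0.4 Hz on a 256-point grid.  SD1 is
computed as RMSSD/√2 (an exact identity); SampEn uses m = 2,
r = 0.2·SDNN (missing for constant series); DFA slopes over boxes 4–11
(α1) and 12–64 (α2).  Note the textbook DFA estimator is biased upward
at the smallest boxes: white noise yields α1 ≈ 0.61 over boxes 4–11 (and
α2 ≈ 0.50), which the tests assert as computed.

Morphological summaries (mean/median/min/max/IQR, quartiles by midpoint
interpolation) are taken per measure over the beats where the measure is
present; beats labelled `none` are excluded from waveform statistics but
counted in `NoneRatio`.  Amplitudes are relative to the QRS-onset
isoelectric level; areas are trapezoidal between signal and isoelectric
line (mV·ms); QTc by both Bazett and Fridericia.  Missing values are
explicit NaN and are median-imputed *inside* the training fold only.

## Model selection and evaluation

mRMR ranks features greedily by mutual information with the label
(10-bin quantile discretisation) minus mean MI with the already-selected
set; the energy threshold — a searched hyperparameter — keeps the
smallest ranked prefix whose cumulative relevance reaches that fraction
of the total.  The hyperparameter search is sequential model-based
optimisation: a Matérn-5/2 Gaussian process with fixed kernel
hyperparameters on the unit cube, expected improvement over 256 random
candidates per iteration, first third of the budget random; the whole
search is deterministic for a fixed seed.  Class imbalance is handled by
a searched positive-class weight.  "Stratified by patients" is
implemented as patient-disjoint inner folds — the reading consistent
with the no-leakage requirement.  Folds that end up single-class score
0.5 with a warning.

Evaluation: rank-based AUROC (ties count one half, equal to the
normalised Mann–Whitney U); mean ± SD over the outer repeats; ROC
envelopes by vertical averaging on a 101-point FPR grid (median and
IQR).  The feature screen compares *recordings* (median over retained
windows — the aggregation the recording-level comparison needs for
independence; mean available), two-sided Mann–Whitney with the exact
null when both groups are ≤8 without ties, tie-corrected normal
approximation otherwise; flat P < 0.05 with an optional
Benjamini–Hochberg switch, off by default.

When a cohort is smaller than the design's default test-set sizes (10
positive / 130 negative patients per repeat), test sets scale as
⌈0.2 × class size⌉.

## Problem sizes

The package defaults target desk-scale experiments: 1-hour recordings at
128 Hz (two 30-min windows per recording), cohorts of tens to hundreds
of patients.  All window/exclusion rules scale linearly and 24 h
recordings are supported.  With 2 windows per recording the 24-hour
six-good-windows rule would exclude everything, so desk-scale
configurations set `min_good_windows` to match the recording length; the
constant 6 remains the default.  The test suite builds one default-effect
cohort (40 C1 / 160 C0, 1 h, 128 Hz) and one zero-effect cohort (20/60)
per session, and the screening-recovery check uses twenty 12/24 cohorts
of 30-min recordings — sizes chosen by an a-priori power analysis on the
generator's ground-truth RR series (PIP screen power >0.99 at that n).

## Known limitations

- The beat classifier's rule thresholds are heuristics tuned to the
  generator's morphology family; real-world bundle-branch blocks,
  aberrant conduction, or fusion-heavy ectopy would need the thresholds
  revisited (they are all parameters).
- Sub-sample R refinement assumes a locally parabolic peak; heavily
  clipped or saturated R waves would defeat it.
- The Lomb–Scargle band powers are reported without windowing
  corrections; absolute power values are comparable within this pipeline
  but not calibrated against other HRV software.
- The generator's null cohort (effect scale 0) still contains PVCs and
  noise — it nulls the *class contrast*, not the physiology.
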