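"""End-to-end orchestration: simulate -> filter/window -> quality -> features
-> nested-CV training -> evaluation, with a manifest of every exclusion.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so each stage is independently
reproducible.  The feature table is cached on disk keyed by a hash of the
upstream configuration; an unchanged configuration reuses it byte for
byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import evaluation as ev
from . import features as feat
from . import quality as qual
from .preprocess import FilterSpec, apply_filters, split_windows
from .synthetic import CohortSpec, default_param_dists, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "quality", "features", "train")


@dataclass
class PipelineConfig:
    """Fully serialisable configuration of one pipeline run."""

    n_c0: int = 160
    n_c1: int = 40
    duration_h: float = 1.0
    fs: float = 128.0
    effect_size_scale: float = 1.0
    recordings_per_patient: int = 1
    passband_low: float = 0.67
    passband_high: float = 100.0
    notch_freq: float = 50.0
    window_min: float = 30.0
    bsqi_threshold: float = 0.8
    min_good_windows: int = 6
    vt_run_prob: float = 0.6
    variants: tuple = ("hrv+mor",)
    outer_repeats: int = 10
    inner_folds: int = 4
    search_iterations: int = 50
    test_c1: int = 10
    test_c0: int = 130
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["variants"] = list(self.variants)
        return d


def validate_config(raw: dict) -> tuple[PipelineConfig, list[str]]:
    """Fill defaults and collect *all* inconsistencies, not just the first."""
    errors = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for k in raw:
        if k not in known:
            errors.append(f"unknown config key: {k}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    if isinstance(cfg.variants, (list, tuple)):
        cfg.variants = tuple(cfg.variants)
    if not 0.0 <= cfg.bsqi_threshold <= 1.0:
        errors.append("bsqi threshold must be in [0,1]")
    if cfg.min_good_windows < 0:
        errors.append("min_good_windows must be non-negative")
    if cfg.passband_high >= 0.5 * cfg.fs:
        logger.warning("passband_high %.3g clipped at runtime (fs=%.3g)",
                       cfg.passband_high, cfg.fs)
    for v in cfg.variants:
        if v not in clf.VARIANTS:
            errors.append(f"unknown model variant: {v}")
    if cfg.n_c0 < 0 or cfg.n_c1 < 0 or cfg.duration_h <= 0 or cfg.fs <= 0:
        errors.append("cohort sizes must be >= 0 and duration/fs positive")
    return cfg, errors


def _config_hash(cfg: PipelineConfig, keys: tuple) -> str:
    d = {k: cfg.to_dict()[k] for k in keys}
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def stage_seeds(seed: int, n: int = len(STAGES)) -> dict:
    """Deterministic per-stage seeds from one global seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(STAGES, children)}


def extract_cohort_features(cfg: PipelineConfig, seed: int | None = None,
                            keep_ground_truth: bool = False):
    """Simulate the cohort and run it through quality gating and features.

    Returns (features table, manifest dict[, ground truth list]).
    """
    seeds = stage_seeds(seed if seed is not None else cfg.seed)
    spec = CohortSpec(
        n_c0=cfg.n_c0, n_c1=cfg.n_c1,
        recordings_per_patient=cfg.recordings_per_patient,
        duration_h=cfg.duration_h, fs=cfg.fs,
        params=default_param_dists(),
        effect_size_scale=cfg.effect_size_scale,
        vt_run_prob=cfg.vt_run_prob,
        seed=seeds["simulate"],
    )
    fspec = FilterSpec(passband_low=cfg.passband_low,
                       passband_high=cfg.passband_high,
                       notch_freq=cfg.notch_freq)
    rows: list[dict] = []
    gts: list = []
    manifest = {
        "n_recordings": 0, "n_recordings_excluded": 0,
        "windows_total": 0, "windows_retained": 0,
        "windows_excluded_quality": 0, "windows_excluded_vt": 0,
        "windows_in_excluded_recordings": 0,
    }
    for profile, rec, gt in simulate_cohort(spec):
        manifest["n_recordings"] += 1
        filt = apply_filters(rec, fspec)
        windows = split_windows(filt, cfg.window_min)
        detections = qual.detect_all_leads(filt)
        qual.score_windows(windows, filt, detections=detections)
        retained, report = qual.apply_exclusions(
            filt, windows, threshold=cfg.bsqi_threshold,
            min_good_windows=cfg.min_good_windows)
        manifest["windows_total"] += report.n_windows_total
        if report.recording_excluded:
            manifest["n_recordings_excluded"] += 1
            manifest["windows_in_excluded_recordings"] += report.n_windows_total
        else:
            manifest["windows_excluded_quality"] += report.n_windows_excluded_quality
            manifest["windows_excluded_vt"] += report.n_windows_excluded_vt
            manifest["windows_retained"] += len(retained)
            rows.extend(feat.features_for_recording(filt, retained, detections))
        if keep_ground_truth:
            gts.append((profile, rec.recording_id,
                        [w.window_index for w in retained], gt))
    table = feat.assemble_features(rows)
    if keep_ground_truth:
        return table, manifest, gts
    return table, manifest


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage, write artefacts + manifest, return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    feature_keys = ("n_c0", "n_c1", "duration_h", "fs", "effect_size_scale",
                    "recordings_per_patient", "passband_low", "passband_high",
                    "notch_freq", "window_min", "bsqi_threshold",
                    "min_good_windows", "vt_run_prob", "seed")
    fhash = _config_hash(cfg, feature_keys)
    cache = outdir / f"features-{fhash}.csv"
    manifest_cache = outdir / f"manifest-{fhash}.json"
    if cache.exists() and manifest_cache.exists():
        logger.info("reusing cached feature table %s", cache.name)
        table = pd.read_csv(cache)
        manifest = json.loads(manifest_cache.read_text())
        manifest["cache_hit"] = True
    else:
        table, manifest = extract_cohort_features(cfg)
        table.to_csv(cache, index=False)
        manifest["cache_hit"] = False
        manifest_cache.write_text(json.dumps(manifest, indent=1))

    patients = (table.groupby("patient_id")["label"].first()
                .reset_index())
    plan = clf.make_splits(patients, outer_repeats=cfg.outer_repeats,
                           test_c1=cfg.test_c1, test_c0=cfg.test_c0,
                           seed=seeds["train"])
    screen = ev.mann_whitney_screen(
        table, feat.PI_FEATURES + feat.HRV_FEATURES + feat.MOR_FEATURES)
    reports = []
    for variant in cfg.variants:
        results = clf.run_nested_cv(table, variant, plan,
                                    n_iter=cfg.search_iterations,
                                    seed=seeds["train"])
        reports.append(ev.build_report(results, variant=variant, screen=screen))
    ev.write_report(reports, outdir)
    manifest["auroc"] = {r.variant: {"mean": r.mean_auroc, "sd": r.sd_auroc}
                         for r in reports}
    manifest["config"] = cfg.to_dict()
    manifest["stage_seeds"] = seeds
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
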