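"""Statistical screening, AUROC, and report generation.

Features are screened with the two-sided Mann--Whitney U test comparing
C0 vs C1 at the recording level (median over each recording's retained
windows), flat significance criterion P < 0.05 (a Benjamini--Hochberg
option exists but is off by default, matching the flat criterion).  AUROC
is computed rank-based -- U/(n1*n0) with average ranks for ties -- which
equals the probability that a random positive outranks a random negative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ALPHA = 0.05
FPR_GRID = np.linspace(0.0, 1.0, 101)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUROC with tie handling (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(scores)
    u = float(np.sum(ranks[labels == 1])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def mann_whitney_screen(features_df: pd.DataFrame, feature_cols: list,
                        agg: str = "median", alpha: float = ALPHA,
                        bh_correct: bool = False) -> pd.DataFrame:
    """Per-feature two-sided Mann--Whitney test, C0 vs C1 recordings.

    Window rows are first aggregated per recording (median by default) so
    observations are independent recordings.  The exact null distribution
    is used when both groups have <= 8 observations and no ties; otherwise
    the tie-corrected normal approximation.  Rows are sorted by p-value.
    """
    rec = (features_df.groupby("recording_id")
           .agg({**{c: agg for c in feature_cols}, "label": "first"}))
    g0 = rec[rec["label"] == 0]
    g1 = rec[rec["label"] == 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both classes must be nonempty")
    rows = []
    for c in feature_cols:
        x = g0[c].dropna().to_numpy()
        y = g1[c].dropna().to_numpy()
        if len(x) == 0 or len(y) == 0:
            rows.append((c, float("nan"), float("nan"), float("nan"), 1.0))
            continue
        if np.ptp(np.concatenate([x, y])) == 0:
            rows.append((c, float(np.median(x)), float(np.median(y)),
                         len(x) * len(y) / 2.0, 1.0))
            continue
        no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append((c, float(np.median(x)), float(np.median(y)),
                     float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["feature", "c0_median", "c1_median",
                                      "U", "p_value"])
    if bh_correct:
        m = len(out)
        order = np.argsort(out["p_value"].to_numpy())
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in list(enumerate(order))[::-1]:
            prev = min(prev, out["p_value"].iloc[idx] * m / (rank + 1))
            adj[idx] = prev
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out.sort_values("p_value").reset_index(drop=True)


def roc_curve_points(scores: np.ndarray, labels: np.ndarray):
    """(FPR, TPR) arrays by threshold sweep over unique scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # collapse runs of tied scores
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), len(y) - 1]
    tpr = np.r_[0.0, tps[distinct] / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps[distinct] / max(fps[-1], 1)]
    return fpr, tpr


@dataclass
class EvalReport:
    """Per-variant evaluation across the outer repeats."""

    variant: str
    aurocs: list = field(default_factory=list)
    mean_auroc: float = float("nan")
    sd_auroc: float = float("nan")
    roc_median: np.ndarray | None = None
    roc_q1: np.ndarray | None = None
    roc_q3: np.ndarray | None = None
    importances: dict = field(default_factory=dict)
    screen: pd.DataFrame | None = None


def build_report(repeat_results: list[dict], variant: str = "",
                 screen: pd.DataFrame | None = None) -> EvalReport:
    """Aggregate outer repeats: mean +/- SD AUROC, ROC envelope, importances.

    The ROC envelope is computed by vertical averaging: each repeat's ROC
    is interpolated onto a common 101-point FPR grid and the median and
    quartiles are taken pointwise.
    """
    if not repeat_results:
        raise ValueError("need at least one completed repeat")
    aurocs = [r["auroc"] for r in repeat_results if np.isfinite(r["auroc"])]
    mean = float(np.mean(aurocs))
    if len(aurocs) > 1:
        sd = float(np.std(aurocs, ddof=1))
    else:
        sd = 0.0
        logger.warning("single repeat: SD reported as 0")
    tprs = []
    for r in repeat_results:
        if len(set(r["labels"])) < 2:
            continue
        fpr, tpr = roc_curve_points(r["probs"], r["labels"])
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
    tprs = np.array(tprs) if tprs else np.zeros((1, len(FPR_GRID)))
    imp: dict = {}
    for r in repeat_results:
        for k, v in r["model"].importances.items():
            imp[k] = imp.get(k, 0.0) + v / len(repeat_results)
    return EvalReport(
        variant=variant,
        aurocs=aurocs,
        mean_auroc=mean,
        sd_auroc=sd,
        roc_median=np.median(tprs, axis=0),
        roc_q1=np.percentile(tprs, 25, axis=0),
        roc_q3=np.percentile(tprs, 75, axis=0),
        importances=dict(sorted(imp.items(), key=lambda kv: -kv[1])),
        screen=screen,
    )


def write_report(reports: list[EvalReport], outdir) -> None:
    """Serialise reports: CSV summary + JSON + ROC figure (one panel/variant)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = pd.DataFrame(
        [{"variant": r.variant, "mean_auroc": r.mean_auroc,
          "sd_auroc": r.sd_auroc, "n_repeats": len(r.aurocs)} for r in reports])
    summary.to_csv(outdir / "auroc_summary.csv", index=False)
    blob = {r.variant: {"aurocs": list(map(float, r.aurocs)),
                        "mean": r.mean_auroc, "sd": r.sd_auroc,
                        "top_features": dict(list(r.importances.items())[:15])}
            for r in reports}
    (outdir / "report.json").write_text(json.dumps(blob, indent=2))
    for r in reports:
        if r.screen is not None:
            r.screen.to_csv(outdir / f"screen_{r.variant}.csv", index=False)
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, max(len(reports), 1),
                                 figsize=(4 * max(len(reports), 1), 4),
                                 squeeze=False)
        for ax, r in zip(axes[0], reports):
            ax.fill_between(FPR_GRID, r.roc_q1, r.roc_q3, alpha=0.3,
                            label="IQR")
            ax.plot(FPR_GRID, r.roc_median, label="median")
            ax.plot([0, 1], [0, 1], "k--", lw=0.8)
            ax.set_title(f"{r.variant}: AUROC {r.mean_auroc:.2f}±{r.sd_auroc:.2f}")
            ax.set_xlabel("FPR")
            ax.set_ylabel("TPR")
            ax.legend(loc="lower right")
        fig.tight_layout()
        fig.savefig(outdir / "roc.png", dpi=120)
        plt.close(fig)
    except Exception as exc:  # plotting must never break the pipeline
        logger.warning("ROC figure not written: %s", exc)
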