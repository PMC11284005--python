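"""Window-level gradient boosting under patient-wise nested cross-validation.

Design: an outer loop of repeated random patient-disjoint train/test
splits; an inner 4-fold cross-validation (folds partitioned by patient)
drives sequential model-based hyperparameter search over the XGBoost
configuration *and* the mRMR energy threshold; the tuned model is refit on
all training windows and test patients are scored by the median predicted
probability over all their retained windows.

The optimizer is a Gaussian-process surrogate with expected improvement
over unit-cube-normalised hyperparameters — deterministic for a fixed
seed.  mRMR ranks features greedily by mutual information relevance minus
mean redundancy on quantile-discretised features; the energy threshold
keeps the smallest ranked prefix whose cumulative relevance reaches the
requested fraction of the total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from xgboost import XGBClassifier

from .evaluation import auroc
from .features import HRV_FEATURES, MOR_FEATURES, PI_FEATURES

logger = logging.getLogger(__name__)

VARIANTS = {
    "pi": PI_FEATURES,
    "hrv": HRV_FEATURES,
    "mor": MOR_FEATURES,
    "hrv+mor": HRV_FEATURES + MOR_FEATURES,
    "pi+hrv+mor": PI_FEATURES + HRV_FEATURES + MOR_FEATURES,
}

#: hyperparameter space: name -> (low, high, kind)
DEFAULT_SPACE = {
    "mrmr_energy": (0.3, 1.0, "float"),
    "n_estimators": (50, 300, "int"),
    "max_depth": (2, 6, "int"),
    "learning_rate": (0.02, 0.3, "log"),
    "subsample": (0.6, 1.0, "float"),
    "colsample_bytree": (0.5, 1.0, "float"),
    "min_child_weight": (1, 10, "int"),
    "scale_pos_weight": (1.0, 20.0, "log"),
}
SEARCH_ITERATIONS = 50
INNER_FOLDS = 4


@dataclass
class SplitPlan:
    """Outer-loop patient-disjoint train/test splits."""

    repeats: list = field(default_factory=list)  # (train_ids, test_ids)
    test_c1: int = 10
    test_c0: int = 130
    seed: int = 0


@dataclass
class TrainedModel:
    model: XGBClassifier
    features: list
    params: dict
    variant: str
    seed: int
    medians: pd.Series
    importances: dict = field(default_factory=dict)


@dataclass
class PatientScore:
    patient_id: str
    window_probs: np.ndarray
    label: int

    @property
    def prob(self) -> float:
        return float(np.median(self.window_probs))


def make_splits(patients: pd.DataFrame, outer_repeats: int = 10,
                test_c1: int = 10, test_c0: int = 130, seed: int = 0) -> SplitPlan:
    """Repeated random patient-level splits with configured test counts.

    ``patients`` has columns patient_id, label (0/1).  The design test
    counts assume a clinic-scale cohort; on smaller cohorts each count is
    capped at ceil(0.2 x class size) so the test set never swallows a
    class (testing on most of a class makes held-out associations of
    noise features anti-correlate with the training remainder, biasing
    AUROC below chance).
    """
    rng = np.random.default_rng(seed)
    ids1 = np.sort(patients.loc[patients["label"] == 1, "patient_id"].unique())
    ids0 = np.sort(patients.loc[patients["label"] == 0, "patient_id"].unique())
    n1, n0 = len(ids1), len(ids0)
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 patients per class")
    k1 = min(test_c1, max(1, int(np.ceil(0.2 * n1))))
    k0 = min(test_c0, max(1, int(np.ceil(0.2 * n0))))
    plan = SplitPlan(test_c1=k1, test_c0=k0, seed=seed)
    for _ in range(outer_repeats):
        t1 = rng.choice(ids1, size=k1, replace=False)
        t0 = rng.choice(ids0, size=k0, replace=False)
        test = set(t1) | set(t0)
        train = [p for p in np.concatenate([ids0, ids1]) if p not in test]
        plan.repeats.append((sorted(train), sorted(test)))
    return plan


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------

def _discretize(x: np.ndarray, bins: int = 10) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), x).astype(np.int64)


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two small-integer label arrays."""
    ka, kb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])))


def mrmr_rank(X: pd.DataFrame, y: np.ndarray, bins: int = 10
              ) -> tuple[list, np.ndarray]:
    """Greedy mRMR ordering of all features; returns (order, relevances).

    Relevance = mutual information with the label on quantile-discretised
    features; redundancy = mean MI with the already-selected set; each step
    adds argmax(relevance - redundancy).
    """
    cols = list(X.columns)
    if len(cols) < 1:
        raise ValueError("need at least one feature")
    yv = np.asarray(y).astype(np.int64)
    disc = {c: _discretize(X[c].to_numpy()) for c in cols}
    rel = np.array([_mi(disc[c], yv) for c in cols])
    order_idx = [int(np.argmax(rel))]
    remaining = [i for i in range(len(cols)) if i != order_idx[0]]
    red_sum = np.zeros(len(cols))
    while remaining:
        last = order_idx[-1]
        for i in remaining:
            red_sum[i] += _mi(disc[cols[i]], disc[cols[last]])
        scores = [rel[i] - red_sum[i] / len(order_idx) for i in remaining]
        nxt = remaining[int(np.argmax(scores))]
        order_idx.append(nxt)
        remaining.remove(nxt)
    return [cols[i] for i in order_idx], rel[order_idx]


def mrmr_select(X: pd.DataFrame, y: np.ndarray, energy: float,
                ranking: tuple | None = None) -> list:
    """Smallest mRMR-ordered prefix reaching ``energy`` of total relevance."""
    if not 0.0 < energy <= 1.0:
        raise ValueError("energy must lie in (0, 1]")
    order, rel = ranking if ranking is not None else mrmr_rank(X, y)
    total = float(np.sum(rel))
    if total <= 0:
        return list(order)
    cum = np.cumsum(rel)
    k = int(np.searchsorted(cum, energy * total - 1e-12)) + 1
    return list(order[:min(k, len(order))])


# ---------------------------------------------------------------------------
# sequential model-based optimisation
# ---------------------------------------------------------------------------

def _decode(u: np.ndarray, space: dict) -> dict:
    out = {}
    for ui, (name, (lo, hi, kind)) in zip(u, space.items()):
        if kind == "log":
            v = float(np.exp(np.log(lo) + ui * (np.log(hi) - np.log(lo))))
        else:
            v = float(lo + ui * (hi - lo))
        if kind == "int":
            v = int(round(v))
        out[name] = v
    return out


def smbo_minimize(objective, space: dict, n_iter: int, seed: int,
                  n_init: int | None = None, n_candidates: int = 256):
    """Maximise ``objective`` over the space with a GP surrogate and EI."""
    rng = np.random.default_rng(seed)
    d = len(space)
    n_init = n_init or max(4, n_iter // 3)
    X, yv = [], []
    best_u, best_y = None, -np.inf
    # fixed kernel hyperparameters: adequate on the unit cube, deterministic,
    # and avoids re-optimising the marginal likelihood every iteration
    gp = GaussianProcessRegressor(
        kernel=Matern(length_scale=np.full(d, 0.3), nu=2.5),
        alpha=1e-4, normalize_y=True, optimizer=None,
        random_state=int(seed) % (2 ** 31))
    for it in range(n_iter):
        if it < n_init or len(set(yv)) < 2:
            u = rng.random(d)
        else:
            gp.fit(np.array(X), -np.array(yv))  # GP minimises
            cand = rng.random((n_candidates, d))
            mu, sd = gp.predict(cand, return_std=True)
            fmin = float(np.min(-np.array(yv)))
            sd = np.maximum(sd, 1e-9)
            z = (fmin - mu) / sd
            ei = (fmin - mu) * norm.cdf(z) + sd * norm.pdf(z)
            u = cand[int(np.argmax(ei))]
        y = objective(_decode(u, space))
        X.append(u)
        yv.append(y)
        if y > best_y:
            best_y, best_u = y, u
    return _decode(best_u, space), best_y


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _xgb(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=params["n_estimators"],
        max_depth=params["max_depth"],
        learning_rate=params["learning_rate"],
        subsample=params["subsample"],
        colsample_bytree=params["colsample_bytree"],
        min_child_weight=params["min_child_weight"],
        scale_pos_weight=params["scale_pos_weight"],
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=int(seed) % (2 ** 31),
        verbosity=0,
    )


def _patient_folds(patient_ids: np.ndarray, k: int, rng: np.random.Generator):
    """Partition unique patients into k disjoint folds (window indices)."""
    uniq = np.sort(np.unique(patient_ids))
    perm = rng.permutation(uniq)
    folds = np.array_split(perm, k)
    for f in folds:
        te = np.isin(patient_ids, f)
        yield np.flatnonzero(~te), np.flatnonzero(te)


def patient_auroc(probs: np.ndarray, patient_ids: np.ndarray,
                  labels: np.ndarray) -> float:
    """AUROC of per-patient median probabilities."""
    df = pd.DataFrame({"p": probs, "pid": patient_ids, "y": labels})
    agg = df.groupby("pid").agg(p=("p", "median"), y=("y", "first"))
    if agg["y"].nunique() < 2:
        return 0.5
    return auroc(agg["p"].to_numpy(), agg["y"].to_numpy())


def tune_and_train(train_df: pd.DataFrame, variant: str,
                   space: dict | None = None,
                   n_iter: int = SEARCH_ITERATIONS,
                   inner_folds: int = INNER_FOLDS,
                   seed: int = 0) -> TrainedModel:
    """Inner-CV hyperparameter search, then refit on all training windows.

    Folds are partitioned by patient (no window of a patient crosses a
    fold boundary).  Missing features are median-imputed with medians
    fitted on the fold-train side only; the mRMR ranking per fold is
    cached because only the energy prefix depends on the hyperparameters.
    """
    space = space or dict(DEFAULT_SPACE)
    feats = VARIANTS[variant]
    rng = np.random.default_rng(seed)
    y = train_df["label"].to_numpy()
    pids = train_df["patient_id"].to_numpy()
    X = train_df[feats]

    folds = list(_patient_folds(pids, inner_folds, rng))
    prepared = []
    for tr, te in folds:
        med = X.iloc[tr].median(numeric_only=True)
        Xtr = X.iloc[tr].fillna(med)
        Xte = X.iloc[te].fillna(med)
        if y[tr].min() == y[tr].max() or y[te].min() == y[te].max():
            prepared.append(None)  # single-class fold: scored 0.5
            continue
        ranking = mrmr_rank(Xtr, y[tr]) if len(feats) > 1 else ([feats[0]], np.ones(1))
        prepared.append((Xtr, Xte, tr, te, ranking))

    def objective(params: dict) -> float:
        scores = []
        for prep in prepared:
            if prep is None:
                scores.append(0.5)
                continue
            Xtr, Xte, tr, te, ranking = prep
            sel = mrmr_select(Xtr, y[tr], params["mrmr_energy"], ranking=ranking)
            clf = _xgb(params, seed)
            clf.fit(Xtr[sel], y[tr])
            p = clf.predict_proba(Xte[sel])[:, 1]
            scores.append(patient_auroc(p, pids[te], y[te]))
        return float(np.mean(scores))

    best, best_score = smbo_minimize(objective, space, n_iter, seed)
    logger.info("variant=%s best inner AUROC=%.3f params=%s", variant, best_score, best)

    med = X.median(numeric_only=True)
    Xf = X.fillna(med)
    ranking = mrmr_rank(Xf, y) if len(feats) > 1 else ([feats[0]], np.ones(1))
    sel = mrmr_select(Xf, y, best["mrmr_energy"], ranking=ranking)
    clf = _xgb(best, seed)
    clf.fit(Xf[sel], y)
    imp = dict(zip(sel, clf.feature_importances_.tolist()))
    return TrainedModel(model=clf, features=sel, params=best, variant=variant,
                        seed=seed, medians=med, importances=imp)


def score_patients(model: TrainedModel, test_df: pd.DataFrame) -> list[PatientScore]:
    """Per-window probabilities aggregated to a per-patient median score."""
    X = test_df[VARIANTS[model.variant]].fillna(model.medians)
    probs = model.model.predict_proba(X[model.features])[:, 1]
    out = []
    for pid, grp in test_df.assign(_p=probs).groupby("patient_id"):
        if len(grp) == 0:
            logger.warning("patient %s has no retained windows", pid)
            continue
        out.append(PatientScore(patient_id=str(pid),
                                window_probs=grp["_p"].to_numpy(),
                                label=int(grp["label"].iloc[0])))
    return out


def run_nested_cv(features_df: pd.DataFrame, variant: str,
                  plan: SplitPlan, n_iter: int = SEARCH_ITERATIONS,
                  seed: int = 0) -> list[dict]:
    """Train/evaluate one model variant over every outer repeat."""
    results = []
    for k, (train_ids, test_ids) in enumerate(plan.repeats):
        tr = features_df[features_df["patient_id"].isin(train_ids)]
        te = features_df[features_df["patient_id"].isin(test_ids)]
        assert not set(tr["patient_id"]) & set(te["patient_id"])
        model = tune_and_train(tr, variant, n_iter=n_iter, seed=seed + k)
        scores = score_patients(model, te)
        probs = np.array([s.prob for s in scores])
        labels = np.array([s.label for s in scores])
        results.append({
            "repeat": k,
            "auroc": auroc(probs, labels) if len(set(labels)) > 1 else float("nan"),
            "scores": scores,
            "probs": probs,
            "labels": labels,
            "model": model,
        })
    return results
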