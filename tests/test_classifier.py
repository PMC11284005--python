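"""Splits, mRMR selection, model tuning, and patient aggregation."""

import numpy as np
import pandas as pd
import pytest

from vtscreen.classifier import (
    PatientScore,
    make_splits,
    mrmr_rank,
    mrmr_select,
    patient_auroc,
    score_patients,
    smbo_minimize,
    tune_and_train,
)
from vtscreen.features import HRV_FEATURES, MOR_FEATURES, PI_FEATURES


def _patients(n1, n0):
    return pd.DataFrame({
        "patient_id": [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n0)],
        "label": [1] * n1 + [0] * n0,
    })


class TestMakeSplits:
    def test_default_counts_when_attainable(self):
        plan = make_splits(_patients(49, 1570), outer_repeats=3, seed=0)
        assert plan.test_c1 == 10 and plan.test_c0 == 130
        for train, test in plan.repeats:
            assert len([p for p in test if p.startswith("a")]) == 10
            assert len([p for p in test if p.startswith("b")]) == 130

    def test_patient_disjoint(self):
        plan = make_splits(_patients(20, 50), outer_repeats=5, seed=1)
        for train, test in plan.repeats:
            assert not set(train) & set(test)

    def test_scaled_down_counts(self):
        plan = make_splits(_patients(10, 40), outer_repeats=2, seed=2)
        assert plan.test_c1 == 2 and plan.test_c0 == 8

    def test_deterministic(self):
        a = make_splits(_patients(12, 30), outer_repeats=4, seed=9)
        b = make_splits(_patients(12, 30), outer_repeats=4, seed=9)
        assert a.repeats == b.repeats

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            make_splits(_patients(1, 50))


class TestMrmr:
    def _table(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        informative = y + 0.3 * rng.standard_normal(n)
        data = {"informative": informative, "copy": informative.copy()}
        for i in range(8):
            data[f"noise{i}"] = rng.standard_normal(n)
        return pd.DataFrame(data), y

    def test_informative_first_copy_demoted(self):
        X, y = self._table()
        order, rel = mrmr_rank(X, y)
        assert order[0] in ("informative", "copy")
        assert order[1] not in ("informative", "copy")

    def test_energy_one_selects_all(self):
        X, y = self._table()
        assert len(mrmr_select(X, y, energy=1.0)) == X.shape[1]

    def test_energy_prefix_shrinks(self):
        X, y = self._table()
        small = mrmr_select(X, y, energy=0.5)
        assert 1 <= len(small) < X.shape[1]

    def test_single_feature(self):
        X, y = self._table()
        sel = mrmr_select(X[["informative"]], y, energy=0.3)
        assert sel == ["informative"]

    def test_invalid_energy_rejected(self):
        X, y = self._table()
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                mrmr_select(X, y, energy=bad)


class TestSmbo:
    def test_deterministic(self):
        space = {"x": (0.0, 1.0, "float"), "k": (1, 10, "int")}

        def obj(p):
            return -(p["x"] - 0.3) ** 2 - 0.01 * (p["k"] - 4) ** 2

        a = smbo_minimize(obj, space, n_iter=15, seed=3)
        b = smbo_minimize(obj, space, n_iter=15, seed=3)
        assert a == b

    def test_improves_over_init(self):
        space = {"x": (0.0, 1.0, "float"), "y": (0.0, 1.0, "float")}

        def obj(p):
            return -(p["x"] - 0.62) ** 2 - (p["y"] - 0.31) ** 2

        best, score = smbo_minimize(obj, space, n_iter=25, seed=0)
        assert score > -0.02


def _feature_table(n_pat1=6, n_pat0=12, windows=3, seed=0):
    """Tiny separable window table with real feature column names."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pat1 + n_pat0):
        label = 1 if i < n_pat1 else 0
        for w in range(windows):
            row = {"patient_id": f"p{i:02d}", "recording_id": f"p{i:02d}_r0",
                   "window_index": w, "label": label}
            for c in PI_FEATURES:
                row[c] = rng.random()
            for c in HRV_FEATURES + MOR_FEATURES:
                row[c] = rng.standard_normal()
            row["Vratio"] = label * 0.05 + rng.random() * 0.01
            row["PIP"] = 0.5 + 0.2 * label + 0.05 * rng.standard_normal()
            rows.append(row)
    return pd.DataFrame(rows)


class TestTuneAndTrain:
    def test_recovers_separable_signal(self):
        table = _feature_table()
        model = tune_and_train(table, "hrv+mor", n_iter=4, seed=1)
        assert set(model.features) <= set(HRV_FEATURES + MOR_FEATURES)
        scores = score_patients(model, table)
        probs = np.array([s.prob for s in scores])
        labels = np.array([s.label for s in scores])
        assert patient_auroc(probs, [s.patient_id for s in scores], labels) > 0.9

    def test_deterministic_hyperparameters(self):
        table = _feature_table()
        a = tune_and_train(table, "hrv", n_iter=3, seed=7)
        b = tune_and_train(table, "hrv", n_iter=3, seed=7)
        assert a.params == b.params
        assert a.features == b.features


class TestScorePatients:
    def _model(self):
        return tune_and_train(_feature_table(), "hrv+mor", n_iter=2, seed=0)

    def test_median_aggregation(self):
        s = PatientScore("p", np.array([0.2, 0.9, 0.4]), 1)
        assert s.prob == pytest.approx(0.4)
        s4 = PatientScore("p", np.array([0.2, 0.9, 0.4, 0.6]), 1)
        assert s4.prob == pytest.approx(0.5)

    def test_window_order_invariance(self):
        model = self._model()
        table = _feature_table(seed=5)
        a = score_patients(model, table)
        b = score_patients(model, table.sample(frac=1.0, random_state=3))
        assert {s.patient_id: s.prob for s in a} == \
            {s.patient_id: s.prob for s in b}
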