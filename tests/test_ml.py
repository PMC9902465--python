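"""Feature assembly, Boruta, nested CV, metrics, parameter sensitivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainfc.connectivity import FCMatrix
from brainfc.ml import (
    ConfusionCounts,
    FeatureTable,
    boruta_select,
    compute_metrics,
    counts_from_predictions,
    nested_cv,
    parameter_sensitivity,
    residualize,
    unvectorize,
    vectorize,
)
from oracles import mann_whitney_auc


def _table(seed, n=60, p=10, signal_cols=(), shift=1.0):
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
    x = rng.standard_normal((n, p))
    for c in signal_cols:
        x[y == 1, c] += shift
    names = [f"f{i}" for i in range(p)]
    return FeatureTable(x, y, names)


class TestVectorize:
    def test_fc_ordering_and_count(self):
        w = np.arange(16, dtype=float).reshape(4, 4)
        w = (w + w.T) / 2
        fc = FCMatrix(w, "PC", roi_labels=["A", "B", "C", "D"])
        row, names = vectorize(fc, "PC")
        assert len(row) == 6
        assert names[0] == "PC:A-B" and names[-1] == "PC:C-D"
        np.testing.assert_array_equal(row, [w[0, 1], w[0, 2], w[0, 3],
                                            w[1, 2], w[1, 3], w[2, 3]])

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal((5, 5))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        row, _ = vectorize(FCMatrix(w, "SR"), "SR")
        np.testing.assert_array_equal(unvectorize(row, 5), w)

    def test_asymmetric_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetrize"):
            vectorize(FCMatrix(w, "SR"), "SR")

    def test_dhofc_cluster_pairs(self):
        from brainfc.connectivity import DHOFCResult

        net = np.eye(3)
        res = DHOFCResult(np.array([1, 2, 3]), np.zeros((3, 5)), net, 3)
        row, names = vectorize(res, "dHOFC")
        assert len(row) == 3
        assert names == ["dHOFC:C1-C2", "dHOFC:C1-C3", "dHOFC:C2-C3"]


class TestResidualize:
    def _cov_table(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        motion = rng.lognormal(-2, 0.4, n)
        sex = rng.choice(["M", "F"], n)
        cov = pd.DataFrame({"motion": motion, "sex": sex})
        y = rng.integers(0, 2, n)
        y[:5] = 1
        y[5:10] = 0
        x = np.column_stack([motion, rng.standard_normal(n)])
        return FeatureTable(x, y, ["exact_motion", "noise"], cov)

    def test_feature_equal_to_covariate_vanishes(self):
        t = residualize(self._cov_table(), ["motion", "sex"])
        assert np.max(np.abs(t.matrix[:, 0])) < 1e-10

    def test_residuals_orthogonal_to_design(self):
        t0 = self._cov_table(1)
        t = residualize(t0, ["motion", "sex"])
        motion = t0.covariates["motion"].to_numpy()
        for k in range(t.n_features):
            r = t.matrix[:, k]
            if r.std() < 1e-10:  # feature fully explained by the design
                continue
            assert abs(np.corrcoef(r, motion)[0, 1]) < 1e-8

    def test_independent_covariates_leave_demeaned_feature(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            cov = pd.DataFrame({"motion": rng.lognormal(-2, 0.4, n)})
            x = rng.standard_normal((n, 1))
            y = rng.integers(0, 2, n)
            t = FeatureTable(x, y, ["f"], cov)
            r = residualize(t, ["motion"]).matrix[:, 0]
            demeaned = x[:, 0] - x[:, 0].mean()
            hits += np.corrcoef(r, demeaned)[0, 1] > 0.99
        assert hits >= 18


class TestBoruta:
    def test_label_copy_accepted(self):
        ok = 0
        for seed in range(10):
            t = _table(seed, n=100, p=10)
            t.matrix[:, 0] = t.labels + 0.01 * np.random.default_rng(seed).standard_normal(100)
            mask = boruta_select(t, rf_params={"n_estimators": 50},
                                 max_rounds=20, seed=seed)
            ok += mask[0]
        assert ok >= 9

    def test_pure_noise_rarely_accepted(self):
        total = 0
        for seed in range(10):
            t = _table(seed + 100, n=100, p=50)
            mask = boruta_select(t, rf_params={"n_estimators": 50},
                                 max_rounds=15, seed=seed)
            total += mask.sum()
        assert total / 10 <= 1.0

    def test_planted_features_found(self):
        ok = 0
        for seed in range(10):
            t = _table(seed + 200, n=200, p=45, signal_cols=(0, 1, 2, 3, 4), shift=0.8)
            mask = boruta_select(t, rf_params={"n_estimators": 100},
                                 max_rounds=20, seed=seed)
            ok += mask[:5].sum() >= 4
        assert ok >= 8

    def test_single_class_rejected(self):
        t = _table(0)
        t.labels[:] = 1
        with pytest.raises(ValueError):
            boruta_select(t)


class TestMetrics:
    def test_printed_formula_example(self):
        m = compute_metrics(ConfusionCounts(tp=3, tn=2, fp=1, fn=2))
        assert m["acc"] == pytest.approx(0.625)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.6)
        assert m["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_separation_auc_one(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        m = compute_metrics(counts_from_predictions(y, (s > 0.5).astype(int)), s, y)
        assert m["auc"] == 1.0

    def test_all_tied_scores_auc_half(self):
        y = np.array([0, 1, 0, 1])
        s = np.zeros(4)
        m = compute_metrics(counts_from_predictions(y, np.zeros(4, int)), s, y)
        assert m["auc"] == 0.5

    def test_zero_denominator_flagged(self):
        m = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert m["precision"] == 0.0 and "precision_undefined" in m["flags"]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(tp=st.integers(0, 50), tn=st.integers(0, 50),
           fp=st.integers(0, 50), fn=st.integers(0, 50))
    def test_metric_identities_on_random_counts(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        assert m["acc"] == (tp + tn) / (tp + tn + fp + fn)
        if tp + fp:
            assert m["precision"] == tp / (tp + fp)
        if tp + fn:
            assert m["recall"] == tp / (tp + fn)
        if m["precision"] + m["recall"] > 0:
            assert m["f1"] == pytest.approx(
                2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"]))

    def test_auc_matches_mann_whitney(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            s = rng.standard_normal(30).round(1)  # ties likely
            m = compute_metrics(counts_from_predictions(y, (s > 0).astype(int)), s, y)
            assert m["auc"] == pytest.approx(mann_whitney_auc(y, s), abs=1e-12)


class TestNestedCV:
    def test_label_copy_gives_perfect_auc(self):
        t = _table(0, n=60, p=5)
        t.matrix[:, 0] = t.labels.astype(float)
        rep = nested_cv(t, classifier="logistic", outer_k=5, inner_k=3, seed=0,
                        selector=None)
        assert rep.mean_metric("auc") == 1.0

    def test_folds_partition_and_stratify(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.r_[np.ones(25, int), np.zeros(35, int)]
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = np.zeros(60, int)
        for _, te in skf.split(np.zeros(60), y):
            seen[te] += 1
            frac = y[te].mean()
            assert abs(frac - 25 / 60) < 1.5 / len(te) + 1e-9
        assert np.all(seen == 1)

    def test_report_structure(self):
        t = _table(1, n=60, p=8, signal_cols=(0,), shift=2.0)
        rep = nested_cv(t, classifier="svm_rbf", outer_k=5, inner_k=3, seed=1,
                        boruta_params={"rf_params": {"n_estimators": 25},
                                       "max_rounds": 10})
        assert rep.n_folds == 5
        assert len(rep.selected_features) == 5
        assert len(rep.chosen_params) == 5


class TestParameterSensitivity:
    def test_single_point_grid(self):
        t = _table(2, n=60, p=6, signal_cols=(0,), shift=1.0)
        df, best = parameter_sensitivity({(50,): t}, folds=5, seed=0)
        assert best == (50,)
        assert len(df) == 1

    def test_duplicate_grid_point_identical_auc(self):
        t = _table(3, n=60, p=6, signal_cols=(0,), shift=1.0)
        df, best = parameter_sensitivity({(1,): t, (2,): t}, folds=5, seed=0)
        aucs = df["mean_auc"].to_numpy()
        assert aucs[0] == aucs[1]
        assert best == (1,)  # tie -> smallest parameter

    def test_missing_point_excluded(self):
        t = _table(4, n=60, p=6, signal_cols=(0,), shift=1.0)
        with pytest.warns(UserWarning, match="missing"):
            df, best = parameter_sensitivity({(1,): None, (2,): t}, folds=5, seed=0)
        assert best == (2,)
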