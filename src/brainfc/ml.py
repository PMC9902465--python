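"""Feature assembly, Boruta selection, nested cross-validation and metrics.

The evaluation protocol is a stratified nested cross-validation: the outer
folds (10 by default) estimate generalization, and inside each outer
training set a Boruta-style shadow-feature selection picks the informative
features and an inner 5-fold grid search picks the classifier
hyperparameters by AUC.  The outer test rows are never touched during
selection or tuning; the whole procedure is a deterministic function of the
global seed and the training data, which the poisoning test in the suite
verifies by corrupting test rows and checking that no decision changes.

A separate, simpler protocol (plain stratified 10-fold with a fixed RBF SVM)
serves the parameter-sensitivity analysis used to choose measure parameters
(window length / cluster count / λ grids) before the nested evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.preprocessing import StandardScaler
from sklearn.ensemble import (
    AdaBoostClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from brainfc.connectivity import FCMatrix, DHOFCResult, pair_index


@dataclass
class FeatureTable:
    """Subjects x features with labels and a covariate table."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("one label per row required")
        if len(self.feature_names) != self.matrix.shape[1]:
            raise ValueError("one name per feature required")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix must be finite")
        if self.covariates is not None and len(self.covariates) != self.matrix.shape[0]:
            raise ValueError("one covariate row per subject required")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        cov = self.covariates.iloc[idx].reset_index(drop=True) \
            if self.covariates is not None else None
        return FeatureTable(self.matrix[idx], self.labels[idx],
                            list(self.feature_names), cov)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class CVReport:
    """Aggregated nested-CV result."""

    fold_metrics: list[dict]
    selected_features: list[list[str]]
    chosen_params: list[dict]
    classifier: str
    seed: int

    def mean_metric(self, name: str) -> float:
        return float(np.mean([m[name] for m in self.fold_metrics]))

    @property
    def n_folds(self) -> int:
        return len(self.fold_metrics)


def vectorize(obj, modality_tag: str) -> tuple[np.ndarray, list[str]]:
    """Flatten an FC matrix / dHOFC network into a named feature row.

    FC matrices use the upper triangle excluding the diagonal, row-major
    (i<j); names carry the ROI-pair (or cluster-pair) identity.
    """
    if isinstance(obj, FCMatrix):
        if not obj.is_symmetric(tol=1e-10):
            raise ValueError("asymmetric FC matrix: symmetrize() it first")
        n = obj.n_rois
        iu = np.triu_indices(n, k=1)
        row = obj.values[iu]
        names = [f"{modality_tag}:{obj.roi_labels[i]}-{obj.roi_labels[j]}"
                 for i, j in zip(*iu)]
        return row, names
    if isinstance(obj, DHOFCResult):
        k = obj.k_clusters
        iu = np.triu_indices(k, k=1)
        row = obj.network[iu]
        names = [f"{modality_tag}:C{i + 1}-C{j + 1}" for i, j in zip(*iu)]
        return row, names
    if hasattr(obj, "values") and hasattr(obj, "mask"):  # VoxelMap
        vals = obj.values[obj.mask]
        coords = np.argwhere(obj.mask)
        names = [f"{modality_tag}:v{x}_{y}_{z}" for x, y, z in coords]
        return vals, names
    raise TypeError("vectorize expects FCMatrix, DHOFCResult or VoxelMap")


def unvectorize(row: np.ndarray, n_rois: int) -> np.ndarray:
    """Inverse of :func:`vectorize` for FC matrices (diagonal set to 0)."""
    out = np.zeros((n_rois, n_rois))
    iu = np.triu_indices(n_rois, k=1)
    out[iu] = row
    return out + out.T


def cohort_feature_table(fcs, labels, covariates, modality_tag: str) -> FeatureTable:
    """Stack per-subject vectorized FC estimates into a FeatureTable."""
    rows, names = zip(*(vectorize(fc, modality_tag) for fc in fcs))
    return FeatureTable(np.vstack(rows), labels, list(names[0]), covariates)


def _encode_covariates(cov: pd.DataFrame, names: list[str]) -> np.ndarray:
    cols = []
    for name in names:
        col = cov[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True)
            cols.append(dummies.to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float)[:, None])
    return np.hstack(cols) if cols else np.empty((len(cov), 0))


def residualize(table: FeatureTable, covariate_names: list[str]) -> FeatureTable:
    """Replace each feature by its OLS residual on intercept + covariates.

    Categorical covariates are one-hot encoded (first level dropped);
    linearly dependent design columns are dropped with a warning.
    """
    if table.covariates is None:
        raise ValueError("table has no covariates")
    x = _encode_covariates(table.covariates, covariate_names)
    design = np.column_stack([np.ones(table.n_subjects), x])
    q, r = np.linalg.qr(design)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1e-300)
    if not keep.all():
        warnings.warn("dropping linearly dependent covariate column(s)", stacklevel=2)
        design = design[:, keep]
        q, _ = np.linalg.qr(design)
    resid = table.matrix - q @ (q.T @ table.matrix)
    return FeatureTable(resid, table.labels, list(table.feature_names),
                        table.covariates)


def boruta_select(
    train_table: FeatureTable,
    rf_params: dict | None = None,
    alpha: float = 0.05,
    max_rounds: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Boruta-style all-relevant selection with shadow features.

    Each round appends a shuffled copy of every still-undecided feature,
    fits a random forest, and scores a "hit" for features whose importance
    beats the best shadow importance.  Features are accepted/rejected by
    binomial tests on their hit counts (Bonferroni-corrected over the
    features still in play); whatever is undecided at ``max_rounds`` is
    rejected.  Returns a boolean mask over the features.
    """
    y = train_table.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    params = {"n_estimators": 300, "max_depth": 5}
    params.update(rf_params or {})
    x = train_table.matrix
    n_feat = x.shape[1]
    rng = np.random.default_rng(seed)
    status = np.zeros(n_feat, dtype=int)  # 0 undecided, 1 accepted, -1 rejected
    hits = np.zeros(n_feat, dtype=int)
    rounds = np.zeros(n_feat, dtype=int)
    for rnd in range(max_rounds):
        active = status != -1  # accepted features stay in the model
        undecided = status == 0
        if not undecided.any():
            break
        xa = x[:, active]
        shadow = xa.copy()
        for c in range(shadow.shape[1]):
            shadow[:, c] = rng.permutation(shadow[:, c])
        rf = RandomForestClassifier(
            random_state=int(rng.integers(2**31 - 1)), **params
        )
        rf.fit(np.hstack([xa, shadow]), y)
        imp = rf.feature_importances_
        real_imp = np.zeros(n_feat)
        real_imp[active] = imp[: xa.shape[1]]
        shadow_max = imp[xa.shape[1]:].max() if shadow.shape[1] else 0.0
        hit = (real_imp > shadow_max) & undecided
        hits[hit] += 1
        rounds[undecided] += 1
        # two-step binomial decisions, Bonferroni over still-undecided features
        n_open = int(undecided.sum())
        a_corr = alpha / max(n_open, 1)
        for f in np.flatnonzero(undecided):
            r, h = rounds[f], hits[f]
            if r < 5:
                continue
            if stats.binom.sf(h - 1, r, 0.5) < a_corr:
                status[f] = 1
            elif stats.binom.cdf(h, r, 0.5) < a_corr:
                status[f] = -1
    return status == 1


def compute_metrics(counts: ConfusionCounts, scores=None, labels=None) -> dict:
    """ACC / precision / recall / F1 from confusion counts, plus AUC.

    Ratios with zero denominators are reported as 0 and flagged.  AUC is the
    trapezoidal area under the ROC curve (tied scores handled by midpoint
    averaging, so all-equal scores give 0.5); it requires ``scores`` and
    ``labels``.
    """
    flags = []
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total
    acc = (tp + tn) / total if total else 0.0
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        precision = 0.0
        flags.append("precision_undefined")
    if tp + fn:
        recall = tp / (tp + fn)
    else:
        recall = 0.0
        flags.append("recall_undefined")
    if precision + recall:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        flags.append("f1_undefined")
    out = {"acc": acc, "precision": precision, "recall": recall, "f1": f1}
    if scores is not None and labels is not None:
        labels = np.asarray(labels)
        scores = np.asarray(scores, dtype=float)
        if len(np.unique(labels)) < 2:
            out["auc"] = 0.0
            flags.append("auc_undefined")
        elif np.ptp(scores) == 0:
            out["auc"] = 0.5
        else:
            out["auc"] = float(roc_auc_score(labels, scores))
    if flags:
        out["flags"] = flags
    return out


def counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    return ConfusionCounts(
        tp=int(((y_pred == 1) & (y_true == 1)).sum()),
        tn=int(((y_pred == 0) & (y_true == 0)).sum()),
        fp=int(((y_pred == 1) & (y_true == 0)).sum()),
        fn=int(((y_pred == 0) & (y_true == 1)).sum()),
    )


def _scaled(est) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


def make_classifier_specs(seed: int = 0) -> dict[str, tuple[object, dict]]:
    """The nine-classifier zoo: (estimator, hyperparameter grid) per name.

    Four basic classifiers, two SVMs, three tree ensembles; grids are small
    artifact defaults since only the search protocol, not particular grids,
    is part of the design.
    """
    return {
        "logistic": (_scaled(LogisticRegression(max_iter=2000)),
                     {"clf__C": [0.01, 0.1, 1.0, 10.0]}),
        "knn": (_scaled(KNeighborsClassifier()),
                {"clf__n_neighbors": [3, 5, 9]}),
        "ridge": (_scaled(RidgeClassifier()),
                  {"clf__alpha": [0.1, 1.0, 10.0]}),
        "gaussian_nb": (_scaled(GaussianNB()), {}),
        "svm_linear": (_scaled(SVC(kernel="linear")),
                       {"clf__C": [0.01, 0.1, 1.0, 10.0]}),
        "svm_rbf": (_scaled(SVC(kernel="rbf")),
                    {"clf__C": [0.1, 1.0, 10.0], "clf__gamma": ["scale"]}),
        "random_forest": (RandomForestClassifier(random_state=seed),
                          {"n_estimators": [100, 300]}),
        "gradient_boosting": (HistGradientBoostingClassifier(random_state=seed),
                              {"learning_rate": [0.05, 0.1]}),
        "adaboost": (AdaBoostClassifier(random_state=seed),
                     {"n_estimators": [50, 100]}),
    }


CLASSIFIER_SPECS = make_classifier_specs()


def _decision_scores(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(x), dtype=float)
    return np.asarray(model.predict_proba(x)[:, 1], dtype=float)


def _inner_grid_search(x, y, estimator, grid: dict, inner_k: int, seed: int) -> dict:
    """Best hyperparameters by mean inner-fold AUC; ties go to grid order."""
    from itertools import product

    if not grid:
        return {}
    keys = list(grid)
    best_params, best_auc = {}, -np.inf
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    for combo in product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        aucs = []
        for tr, te in splits:
            est = clone(estimator).set_params(**params)
            est.fit(x[tr], y[tr])
            scores = _decision_scores(est, x[te])
            if np.ptp(scores) == 0 or len(np.unique(y[te])) < 2:
                aucs.append(0.5)
            else:
                aucs.append(roc_auc_score(y[te], scores))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc + 1e-12:
            best_auc, best_params = mean_auc, params
    return best_params


def nested_cv(
    table: FeatureTable,
    classifier_specs: dict[str, tuple[object, dict]] | None = None,
    classifier: str = "svm_rbf",
    outer_k: int = 10,
    inner_k: int = 5,
    seed: int = 0,
    selector: str | None = "boruta",
    boruta_params: dict | None = None,
) -> CVReport:
    """Nested stratified CV: Boruta selection and inner tuning on the outer
    training set only; metrics on the untouched outer test set.

    If Boruta accepts no feature in a fold, all features are kept for that
    fold (flagged in the chosen-params record) so the classifier can still
    be fit; under a true null this leaves AUC at chance.
    """
    specs = classifier_specs if classifier_specs is not None else make_classifier_specs(seed)
    estimator, grid = specs[classifier]
    y = table.labels
    counts = np.bincount(y)
    if counts.min() < outer_k:
        raise ValueError("need at least outer_k subjects per class")
    skf = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    fold_metrics, selections, chosen = [], [], []
    bparams = dict(boruta_params or {})
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_seed = seed * 1000 + fold
        x_tr, y_tr = table.matrix[tr], y[tr]
        if selector == "boruta":
            mask = boruta_select(
                table.subset_rows(tr),
                rf_params=bparams.get("rf_params"),
                alpha=bparams.get("alpha", 0.05),
                max_rounds=bparams.get("max_rounds", 100),
                seed=fold_seed,
            )
            fallback = not mask.any()
            if fallback:
                mask = np.ones(table.n_features, dtype=bool)
        elif selector is None:
            mask = np.ones(table.n_features, dtype=bool)
            fallback = False
        else:
            raise ValueError(f"unknown selector {selector!r}")
        params = _inner_grid_search(x_tr[:, mask], y_tr, estimator, grid,
                                    inner_k, fold_seed)
        est = clone(estimator)
        if params:
            est.set_params(**params)
        est.fit(x_tr[:, mask], y_tr)
        x_te = table.matrix[te][:, mask]
        scores = _decision_scores(est, x_te)
        preds = np.asarray(est.predict(x_te), int)
        m = compute_metrics(counts_from_predictions(y[te], preds), scores, y[te])
        fold_metrics.append(m)
        selections.append([table.feature_names[i] for i in np.flatnonzero(mask)]
                          if not fallback else [])
        chosen.append({**params, "selection_fallback": fallback})
    return CVReport(fold_metrics, selections, chosen, classifier, seed)


def parameter_sensitivity(
    feature_tables: dict,
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, tuple]:
    """Plain stratified k-fold mean AUC per parameter grid point.

    ``feature_tables`` maps a parameter tuple (e.g. ``(K, L)`` or ``(lam,)``)
    to the FeatureTable computed at that grid point.  Each point is scored by
    mean AUC of an RBF-kernel SVM at the fixed default C=1.0; the argmax is
    returned, ties broken by the smallest parameter values.  Failed grid
    points (None tables) are recorded as missing.
    """
    rows = []
    for point, table in feature_tables.items():
        if table is None:
            warnings.warn(f"grid point {point} missing; excluded from argmax",
                          stacklevel=2)
            rows.append({"point": point, "mean_auc": np.nan})
            continue
        y = table.labels
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        aucs = []
        for tr, te in skf.split(table.matrix, y):
            est = _scaled(SVC(kernel="rbf", C=1.0))
            est.fit(table.matrix[tr], y[tr])
            scores = _decision_scores(est, table.matrix[te])
            if np.ptp(scores) == 0 or len(np.unique(y[te])) < 2:
                aucs.append(0.5)
            else:
                aucs.append(roc_auc_score(y[te], scores))
        rows.append({"point": point, "mean_auc": float(np.mean(aucs))})
    df = pd.DataFrame(rows)
    valid = df.dropna(subset=["mean_auc"])
    if valid.empty:
        raise RuntimeError("no grid point could be evaluated")
    best_auc = valid["mean_auc"].max()
    candidates = sorted(valid.loc[valid["mean_auc"] >= best_auc - 1e-12, "point"])
    return df, candidates[0]
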