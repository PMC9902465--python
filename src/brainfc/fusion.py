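"""Multi-modal fusion: early feature concatenation and multiple kernel learning.

Early fusion concatenates the (already selected) per-modality feature tables
column-wise.  Model-based fusion builds one Gram matrix per modality
(RBF with a median-heuristic bandwidth by default, or linear), learns
nonnegative simplex weights by centered-kernel alignment with the label
kernel, and trains an SVM on the combined precomputed kernel.  Alignment
weighting is convex and deterministic, and is recorded on the fitted model
as a swappable strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.svm import SVC

from brainfc.ml import FeatureTable, _decision_scores


@dataclass
class KernelSet:
    """Per-modality S x S Gram matrices with (after fitting) simplex weights."""

    gram: list[np.ndarray]
    modality_tags: list[str]
    weights: np.ndarray | None = None
    bandwidths: list[float] = field(default_factory=list)
    kernel_kind: str = "rbf"
    train_features: list[np.ndarray] = field(default_factory=list)
    feature_stats: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    raw_grams: list[np.ndarray] = field(default_factory=list)
    trace_scales: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.gram:
            if g.shape[0] != g.shape[1] or np.max(np.abs(g - g.T)) > 1e-8:
                raise ValueError("each Gram must be square symmetric")
            vals = np.linalg.eigvalsh((g + g.T) / 2)
            if vals.min() < -1e-8 * max(vals.max(), 1.0):
                raise ValueError("Gram matrix is not PSD within tolerance")

    @property
    def n_subjects(self) -> int:
        return self.gram[0].shape[0]


def early_fuse(tables: list[FeatureTable]) -> FeatureTable:
    """Column-wise concatenation of per-modality feature tables."""
    if len(tables) == 1:
        return tables[0]
    base = tables[0]
    for t in tables[1:]:
        if t.n_subjects != base.n_subjects or np.any(t.labels != base.labels):
            raise ValueError("tables must cover the same subjects in the same order")
    names: list[str] = []
    for t in tables:
        for nm in t.feature_names:
            names.append(nm if nm not in names else f"{nm}#dup{len(names)}")
    return FeatureTable(
        np.hstack([t.matrix for t in tables]), base.labels, names, base.covariates
    )


def _standardize_train(x: np.ndarray):
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("zero-variance modality")
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd, (mu, sd)


def _center_gram(g: np.ndarray) -> np.ndarray:
    n = g.shape[0]
    h = np.eye(n) - np.ones((n, n)) / n
    return h @ g @ h


def build_kernels(
    tables: list[FeatureTable], kernel_kind: str = "rbf",
    tags: list[str] | None = None, center: bool = True
) -> KernelSet:
    """One centered, trace-normalized Gram per modality from training rows.

    RBF bandwidth is the median pairwise Euclidean distance of the
    standardized training features (the median heuristic); Grams are centered
    and scaled so their trace equals the number of subjects.
    """
    if kernel_kind not in {"rbf", "linear"}:
        raise ValueError("kernel_kind must be 'rbf' or 'linear'")
    grams, bws, feats, stats_, raws, scales = [], [], [], [], [], []
    for t in tables:
        x, st = _standardize_train(t.matrix)
        if kernel_kind == "linear":
            raw = x @ x.T
            bw = 0.0
        else:
            d = pdist(x)
            bw = float(np.median(d)) if d.size else 1.0
            bw = bw if bw > 0 else 1.0
            raw = np.exp(-squareform(d) ** 2 / (2 * bw**2))
        g = _center_gram(raw) if center else raw.copy()
        tr = np.trace(g)
        if tr <= 0:
            raise ValueError("degenerate Gram (nonpositive trace)")
        scale = g.shape[0] / tr
        g = g * scale
        grams.append((g + g.T) / 2)
        bws.append(bw)
        feats.append(x)
        stats_.append(st)
        raws.append(raw)
        scales.append(scale)
    tags = tags or [f"modality{i}" for i in range(len(tables))]
    ks = KernelSet(grams, list(tags), bandwidths=bws, kernel_kind=kernel_kind,
                   train_features=feats, feature_stats=stats_,
                   raw_grams=raws, trace_scales=scales)
    ks.centered = center
    return ks


def _alignment_weights(grams: list[np.ndarray], y: np.ndarray) -> np.ndarray:
    """Centered-kernel-alignment weights, positive part, simplex-normalized."""
    yy = np.where(y == 1, 1.0, -1.0)
    ky = _center_gram(np.outer(yy, yy))
    ky_norm = np.linalg.norm(ky)
    scores = []
    for g in grams:
        gc = _center_gram(g)
        denom = np.linalg.norm(gc) * ky_norm
        scores.append(max(float(np.sum(gc * ky)) / denom, 0.0) if denom > 0 else 0.0)
    scores = np.asarray(scores)
    if scores.sum() == 0:
        return np.full(len(grams), 1.0 / len(grams))
    return scores / scores.sum()


@dataclass
class MKLModel:
    kernels: KernelSet
    svm: SVC
    labels_train: np.ndarray
    regularization: float


def mkl_fit(kernels: KernelSet, labels: np.ndarray, regularization: float = 1.0) -> MKLModel:
    """Alignment-weighted multiple kernel learning with an SVM on the
    combined precomputed Gram.  Weights land on the probability simplex."""
    labels = np.asarray(labels, int)
    if min(np.bincount(labels, minlength=2)[:2]) < 2:
        raise ValueError("need at least 2 subjects per class")
    w = _alignment_weights(kernels.gram, labels)
    kernels.weights = w
    combined = sum(wi * g for wi, g in zip(w, kernels.gram))
    vals = np.linalg.eigvalsh((combined + combined.T) / 2)
    if vals.min() < -1e-6:
        raise ValueError("combined kernel is not PSD after clipping")
    svm = SVC(kernel="precomputed", C=regularization)
    svm.fit(combined, labels)
    return MKLModel(kernels, svm, labels, regularization)


def _cross_gram(model: MKLModel, tables_test: list[FeatureTable]) -> np.ndarray:
    ks = model.kernels
    if len(tables_test) != len(ks.gram):
        raise ValueError("test modalities do not match the trained kernel set")
    combined = None
    for m, t in enumerate(tables_test):
        mu, sd = ks.feature_stats[m]
        xt = (t.matrix - mu) / sd
        xtr = ks.train_features[m]
        if ks.kernel_kind == "linear":
            g = xt @ xtr.T
        else:
            bw = ks.bandwidths[m]
            g = np.exp(-cdist(xt, xtr) ** 2 / (2 * bw**2))
        # center with the training kernel statistics, then apply the same
        # trace normalization as the training Gram
        if getattr(ks, "centered", True):
            raw = ks.raw_grams[m]
            col_means = raw.mean(axis=0)
            total_mean = raw.mean()
            g = g - g.mean(axis=1, keepdims=True) - col_means[None, :] + total_mean
        g = g * ks.trace_scales[m]
        contrib = ks.weights[m] * g
        combined = contrib if combined is None else combined + contrib
    return combined


def mkl_nested_cv(
    tables: list[FeatureTable],
    outer_k: int = 10,
    seed: int = 0,
    kernel_kind: str = "rbf",
    regularization: float = 1.0,
):
    """MKL under the same outer-fold protocol as the single-measure CV.

    Kernels, alignment weights and the SVM are fitted on outer-training rows
    only; metrics come from the untouched outer-test rows.  Returns a
    :class:`~brainfc.ml.CVReport` whose chosen-params record carries the
    learned modality weights per fold.
    """
    from sklearn.model_selection import StratifiedKFold

    from brainfc.ml import CVReport, compute_metrics, counts_from_predictions

    y = tables[0].labels
    for t in tables[1:]:
        if np.any(t.labels != y):
            raise ValueError("tables must cover the same subjects in the same order")
    skf = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    fold_metrics, chosen = [], []
    for tr, te in skf.split(np.zeros(len(y)), y):
        train_tabs = [t.subset_rows(tr) for t in tables]
        test_tabs = [t.subset_rows(te) for t in tables]
        ks = build_kernels(train_tabs, kernel_kind=kernel_kind)
        model = mkl_fit(ks, y[tr], regularization=regularization)
        scores = mkl_predict(model, test_tabs)
        preds = (scores > 0).astype(int)
        fold_metrics.append(compute_metrics(
            counts_from_predictions(y[te], preds), scores, y[te]))
        chosen.append({"weights": model.kernels.weights.tolist()})
    return CVReport(fold_metrics, [[] for _ in fold_metrics], chosen, "mkl", seed)


def mkl_predict(model: MKLModel, tables_test: list[FeatureTable]) -> np.ndarray:
    """Continuous decision scores for test subjects (threshold at 0 for labels).

    Test kernels are computed between test and training subjects with the
    training-fitted standardization and bandwidths.
    """
    g = _cross_gram(model, tables_test)
    return _decision_scores(model.svm, g)
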