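"""Pearson low-order FC and the two high-order FC constructions.

Low-order functional connectivity (LOFC) is the Pearson correlation between
ROI time series.  Topographical high-order FC (tHOFC) correlates two ROIs'
whole-brain connectivity *profiles* ("correlation of correlation"), skipping
the entries that involve either ROI.  Dynamics-based high-order FC (dHOFC)
correlates the sliding-window correlation series of ROI *pairs*; Ward
clustering of the pair series reduces the P x P pair network (P = N(N-1)/2)
to a K x K network of cluster-mean series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, ward
from scipy.spatial.distance import pdist


def _default_labels(n: int) -> list[str]:
    return [f"ROI{i + 1}" for i in range(n)]


@dataclass
class RoiTimeSeries:
    """One subject's T x N matrix of ROI-averaged signals."""

    data: np.ndarray
    roi_labels: list[str] | None = None
    tr_seconds: float = 0.8
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 3:
            raise ValueError("time series must be T x N with T >= 3")
        if self.roi_labels is None:
            self.roi_labels = _default_labels(self.data.shape[1])
        if len(self.roi_labels) != self.data.shape[1]:
            raise ValueError("roi_labels length must match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def constant_columns(self) -> np.ndarray:
        return np.ptp(self.data, axis=0) == 0


@dataclass
class FCMatrix:
    """An N x N connectivity estimate tagged with the estimator that made it."""

    values: np.ndarray
    method_tag: str
    roi_labels: list[str] | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FC matrix contains non-finite entries")
        if self.roi_labels is None:
            self.roi_labels = _default_labels(self.values.shape[0])

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def is_symmetric(self, tol: float = 1e-12) -> bool:
        return bool(np.max(np.abs(self.values - self.values.T)) <= tol)


def pair_index(n_rois: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle pair ordering (i<j), 0-based."""
    return [(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)]


@dataclass
class DynamicFCSet:
    """Windowed pairwise correlations: P pairs x Theta windows."""

    window_series: np.ndarray
    pair_index: list[tuple[int, int]]
    window_length: int
    step: int
    flags: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.window_series.shape[1]

    @property
    def n_pairs(self) -> int:
        return self.window_series.shape[0]


@dataclass
class DHOFCResult:
    """K-cluster reduction of the dynamic pair network."""

    assignments: np.ndarray  # pair -> cluster id in 1..K
    cluster_mean_series: np.ndarray  # K x Theta
    network: np.ndarray  # K x K
    k_clusters: int
    flags: dict = field(default_factory=dict)


def _corrcoef_columns(x: np.ndarray, degenerate_value: float = 0.0):
    """Correlation matrix of columns with an explicit zero-variance policy.

    Returns (corr, degenerate_mask) where degenerate rows/cols involve a
    constant column; those entries are set to ``degenerate_value`` instead of
    NaN so downstream feature matrices stay finite.
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean(axis=0)
    sd = np.sqrt((xc * xc).sum(axis=0))
    degen = sd == 0
    sd_safe = np.where(degen, 1.0, sd)
    xn = xc / sd_safe
    c = np.clip(xn.T @ xn, -1.0, 1.0)
    if degen.any():
        c[degen, :] = degenerate_value
        c[:, degen] = degenerate_value
    np.fill_diagonal(c, 1.0)
    return c, degen


def pearson_fc(series: RoiTimeSeries) -> FCMatrix:
    """Pearson-correlation LOFC matrix: symmetric, unit diagonal, in [-1, 1]."""
    const = series.constant_columns()
    if const.any():
        bad = [series.roi_labels[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant ROI time series (undefined correlation): {bad}")
    c, _ = _corrcoef_columns(series.data)
    return FCMatrix(c, "PC", roi_labels=list(series.roi_labels))


def thofc(lofc: FCMatrix) -> FCMatrix:
    """Topographical HOFC: correlation of LOFC profiles.

    Entry (i, j) is the Pearson correlation between row i and row j of the
    LOFC matrix restricted to indices k with k != i and k != j.  The diagonal
    is 1 by convention.  A zero-variance profile after exclusion yields 0 at
    the affected entries, recorded in ``flags``.
    """
    w = lofc.values
    n = w.shape[0]
    if n < 4:
        raise ValueError("tHOFC needs at least 4 ROIs (profiles too short after exclusions)")
    out = np.eye(n)
    degenerate: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            keep = [k for k in range(n) if k != i and k != j]
            a = w[i, keep]
            b = w[j, keep]
            sa = a.std()
            sb = b.std()
            if sa == 0 or sb == 0:
                out[i, j] = out[j, i] = 0.0
                degenerate.append((i, j))
                continue
            r = float(np.clip(np.corrcoef(a, b)[0, 1], -1.0, 1.0))
            out[i, j] = out[j, i] = r
    flags = {"degenerate_pairs": degenerate} if degenerate else {}
    return FCMatrix(out, "tHOFC", roi_labels=list(lofc.roi_labels), flags=flags)


def n_windows(t_points: int, window_length: int, step: int) -> int:
    """Theta = floor((T - L) / s) + 1."""
    return (t_points - window_length) // step + 1


def sliding_window_fc(
    series: RoiTimeSeries, window_length: int, step: int = 1
) -> DynamicFCSet:
    """Rectangular sliding-window Pearson correlations for every ROI pair.

    Returns a P x Theta matrix (P = N(N-1)/2 pairs in row-major upper-triangle
    order).  A constant segment inside a window gets correlation 0 for its
    pairs, with the (pair, window) locations flagged.
    """
    t, n = series.data.shape
    if not 3 <= window_length <= t:
        raise ValueError(f"window length must be in [3, T={t}]")
    if step < 1:
        raise ValueError("step must be >= 1")
    pairs = pair_index(n)
    theta = n_windows(t, window_length, step)
    iu = np.triu_indices(n, k=1)
    out = np.empty((len(pairs), theta))
    degenerate: list[tuple[int, int]] = []
    for w_idx in range(theta):
        start = w_idx * step
        seg = series.data[start : start + window_length]
        c, degen = _corrcoef_columns(seg)
        out[:, w_idx] = c[iu]
        if degen.any():
            for p_idx, (i, j) in enumerate(pairs):
                if degen[i] or degen[j]:
                    degenerate.append((p_idx, w_idx))
    flags = {"degenerate": degenerate} if degenerate else {}
    return DynamicFCSet(out, pairs, window_length, step, flags=flags)


def ward_cluster_pairs(dyn: DynamicFCSet, k_clusters: int) -> np.ndarray:
    """Ward minimum-variance clustering of window-series rows into K clusters.

    Euclidean distance between rows; deterministic (scipy's Ward linkage with
    its fixed tie ordering).  Returns cluster ids in 1..K, none empty.
    """
    p = dyn.n_pairs
    if not 2 <= k_clusters <= p:
        if k_clusters == 1:
            return np.ones(p, dtype=int)
        raise ValueError(f"k_clusters must be in [1, P={p}]")
    if k_clusters == p:
        return np.arange(1, p + 1)
    linkage = ward(pdist(dyn.window_series))
    labels = fcluster(linkage, t=k_clusters, criterion="maxclust")
    if len(np.unique(labels)) != k_clusters:
        raise RuntimeError("Ward cut did not produce the requested number of clusters")
    return labels.astype(int)


def dhofc_network(dyn: DynamicFCSet, assignments: np.ndarray) -> DHOFCResult:
    """K x K dynamic high-order FC network from cluster-mean window series.

    Each cluster's member pair series are averaged (unweighted); the network
    entry (p, q) is the Pearson correlation of mean series p and q.  Zero
    variance mean series give 0 entries and are flagged.
    """
    assignments = np.asarray(assignments, dtype=int)
    if assignments.shape[0] != dyn.n_pairs:
        raise ValueError("one assignment per pair required")
    k = int(assignments.max())
    if set(np.unique(assignments)) != set(range(1, k + 1)):
        raise ValueError("cluster ids must cover 1..K with no gaps")
    means = np.vstack(
        [dyn.window_series[assignments == c].mean(axis=0) for c in range(1, k + 1)]
    )
    net, degen = _corrcoef_columns(means.T)
    flags = {}
    if degen.any():
        flags["degenerate_clusters"] = (np.flatnonzero(degen) + 1).tolist()
    return DHOFCResult(assignments, means, net, k, flags=flags)


def dhofc(
    series: RoiTimeSeries, window_length: int, k_clusters: int, step: int = 1
) -> DHOFCResult:
    """Convenience driver: sliding windows -> Ward clustering -> K x K network."""
    dyn = sliding_window_fc(series, window_length, step)
    labels = ward_cluster_pairs(dyn, k_clusters)
    return dhofc_network(dyn, labels)
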