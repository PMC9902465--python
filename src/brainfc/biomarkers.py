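"""Discriminative-feature (biomarker) identification.

ROI-wise features: the candidates are the features the nested CV's Boruta
step selected in *every* outer fold; each candidate then gets a two-sample
t-test between groups with Benjamini-Hochberg FDR correction, and modality-
specific top-k rules pick the reported list.  Voxel-wise measures instead
get a whole-group voxel t-map with permutation-based cluster-extent
correction: suprathreshold voxels (|t| above the two-tailed p < 0.001
quantile) form 26-connected clusters, and the cluster-size null is the
distribution of the maximum cluster extent under label permutations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from brainfc.ml import CVReport, FeatureTable


def stable_candidates(report: CVReport) -> list[str]:
    """Features selected in every outer fold (set intersection)."""
    sets = [set(s) for s in report.selected_features]
    if not sets:
        return []
    stable = set.intersection(*sets)
    order = {name: i for i, name in enumerate(report.selected_features[0])}
    return sorted(stable, key=lambda nm: order.get(nm, len(order)))


def group_ttest_fdr(
    table: FeatureTable,
    candidate_names: list[str] | None = None,
    alpha: float = 0.05,
    welch: bool = False,
    selection_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Two-sided two-sample t-test per feature with BH FDR across candidates.

    Pooled-variance (Student) test by default; Welch by flag.  Features with
    zero variance in both groups get p = 1 and a flag.  Returns one row per
    candidate with t, p, BH q, direction and (optionally) the outer-fold
    selection count.
    """
    names = candidate_names if candidate_names is not None else list(table.feature_names)
    idx = [table.feature_names.index(nm) for nm in names]
    y = table.labels
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("both groups need at least 2 subjects")
    g1 = table.matrix[y == 1][:, idx]
    g0 = table.matrix[y == 0][:, idx]
    rows = []
    for k, nm in enumerate(names):
        a, b = g1[:, k], g0[:, k]
        if a.std() == 0 and b.std() == 0:
            t_val, p_val, flag = 0.0, 1.0, True
        else:
            t_val, p_val = stats.ttest_ind(a, b, equal_var=not welch)
            flag = False
        rows.append({
            "feature": nm,
            "t_value": float(t_val),
            "p_value": float(p_val),
            "direction": "case>control" if a.mean() >= b.mean() else "case<control",
            "zero_variance": flag,
        })
    df = pd.DataFrame(rows)
    if len(df):
        _, q, _, _ = multipletests(df["p_value"].to_numpy(), method="fdr_bh")
        df["q_value"] = q
        df["significant"] = df["q_value"] < alpha
    if selection_counts is not None:
        df["selection_count"] = [selection_counts.get(nm, 0) for nm in df["feature"]]
    return df


def rank_and_report(rows: pd.DataFrame, modality: str, alpha: float = 0.05) -> pd.DataFrame:
    """Modality-specific final biomarker rules.

    ``slr``-type: significant rows sorted by p ascending, top 20 kept.
    ``ssgsr``-type: all significant rows kept.  ``dhofc``-type: count each
    cluster's appearances across significant cluster-pair rows and keep the
    10 clusters with the highest counts (ties to the lower cluster id);
    rows touching a kept cluster are reported with the counts attached.
    """
    sig = rows[rows["significant"]].copy() if "significant" in rows else rows.copy()
    kind = modality.lower()
    if kind in {"slr", "top20"}:
        return sig.sort_values("p_value", kind="stable").head(20).reset_index(drop=True)
    if kind in {"ssgsr", "all"}:
        return sig.sort_values("p_value", kind="stable").reset_index(drop=True)
    if kind == "dhofc":
        counts: dict[int, int] = {}
        parsed = []
        for nm in sig["feature"]:
            pair = nm.split(":")[-1]
            a, b = pair.split("-")
            ca, cb = int(a.lstrip("C")), int(b.lstrip("C"))
            parsed.append((ca, cb))
            counts[ca] = counts.get(ca, 0) + 1
            counts[cb] = counts.get(cb, 0) + 1
        top = sorted(counts, key=lambda c: (-counts[c], c))[:10]
        keep_set = set(top)
        keep_rows = [i for i, (ca, cb) in enumerate(parsed)
                     if ca in keep_set or cb in keep_set]
        out = sig.iloc[keep_rows].copy().reset_index(drop=True)
        out.attrs["cluster_counts"] = {c: counts[c] for c in top}
        return out
    raise ValueError(f"unknown modality rule {modality!r}")


_CONN_26 = np.ones((3, 3, 3), dtype=int)


def voxel_cluster_test(
    maps_case: np.ndarray,
    maps_control: np.ndarray,
    mask: np.ndarray,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Voxel t-map with permutation max-cluster-extent correction.

    ``maps_case`` / ``maps_control`` are (subjects, X, Y, Z) stacks of one
    measure's maps.  The two-tailed voxel threshold is the Student-t quantile
    at ``voxel_p``; suprathreshold voxels are clustered with 26-connectivity
    separately per sign; the null distribution of the maximum cluster extent
    is built by relabeling subjects ``n_perm`` times.  Clusters whose extent
    exceeds the (1 − cluster_p) null quantile are reported.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mask = np.asarray(mask, bool)
    x = np.concatenate([maps_case, maps_control], axis=0)
    n1, n0 = maps_case.shape[0], maps_control.shape[0]
    labels = np.r_[np.ones(n1, bool), np.zeros(n0, bool)]
    df = n1 + n0 - 2
    t_crit = stats.t.ppf(1 - voxel_p / 2, df)
    flat = x.reshape(x.shape[0], -1)[:, mask.ravel()]

    def tmap(lab: np.ndarray) -> np.ndarray:
        a, b = flat[lab], flat[~lab]
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        sp = ((lab.sum() - 1) * va + ((~lab).sum() - 1) * vb) / df
        se = np.sqrt(sp * (1 / lab.sum() + 1 / (~lab).sum()))
        se = np.where(se == 0, np.inf, se)
        return (ma - mb) / se

    def max_extent(tv: np.ndarray) -> int:
        worst = 0
        vol = np.zeros(mask.shape)
        vol[mask] = tv
        for signed in (vol > t_crit, vol < -t_crit):
            lab_img, n_c = ndimage.label(signed & mask, structure=_CONN_26)
            if n_c:
                worst = max(worst, int(np.bincount(lab_img.ravel())[1:].max()))
        return worst

    t_obs = tmap(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=int)
    for p in range(n_perm):
        null[p] = max_extent(tmap(rng.permutation(labels)))
    extent_crit = float(np.quantile(null, 1 - cluster_p))

    vol = np.zeros(mask.shape)
    vol[mask] = t_obs
    rows = []
    for sign, signed in (("+", vol > t_crit), ("-", vol < -t_crit)):
        lab_img, n_c = ndimage.label(signed & mask, structure=_CONN_26)
        for c in range(1, n_c + 1):
            sel = lab_img == c
            size = int(sel.sum())
            if size <= extent_crit:
                continue
            tv = vol[sel]
            peak_flat = np.abs(tv).argmax()
            coords = np.argwhere(sel)[peak_flat]
            rows.append({
                "sign": sign,
                "size": size,
                "peak_t": float(tv[peak_flat]) if sign == "+" else float(tv[peak_flat]),
                "peak_x": int(coords[0]),
                "peak_y": int(coords[1]),
                "peak_z": int(coords[2]),
                "extent_threshold": extent_crit,
            })
    return pd.DataFrame(rows, columns=["sign", "size", "peak_t", "peak_x",
                                       "peak_y", "peak_z", "extent_threshold"])
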