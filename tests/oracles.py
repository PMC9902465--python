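"""Independent oracles used by the test suite.

These deliberately avoid the package's own solvers: the convex objectives
are minimized by a generic smooth reformulation handed to
scipy.optimize.minimize (L-BFGS-B), with the ℓ1 norm handled exactly by
positive/negative variable splitting and the group/nuclear norms by an
eps-smoothing whose objective bias (at most n_terms * eps) is orders of
magnitude below the comparison tolerance.  Brute-force double-loop
re-implementations of the correlation-based statistics live here as well.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.stats import rankdata

_OPTS = {"maxiter": 20000, "maxfun": 200000, "ftol": 1e-14, "gtol": 1e-12}


# ---------------------------------------------------------------- sparse FC

def oracle_sr(x: np.ndarray, lam: float) -> float:
    """min ½‖X−XW‖²_F + λ‖W‖₁, diag(W)=0, by split-variable L-BFGS-B.

    W = P − Q with P, Q ≥ 0; the diagonal is excluded from the variables.
    Returns the optimal objective value.
    """
    n = x.shape[1]
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    m = len(off)

    def unpack(v):
        w = np.zeros((n, n))
        pq = v[:m] - v[m:]
        for k, (i, j) in enumerate(off):
            w[i, j] = pq[k]
        return w

    def fun(v):
        w = unpack(v)
        r = x - x @ w
        f = 0.5 * np.sum(r * r) + lam * v.sum()
        g_w = -(x.T @ r)
        g_off = np.array([g_w[i, j] for (i, j) in off])
        grad = np.concatenate([g_off + lam, -g_off + lam])
        return f, grad

    res = minimize(fun, np.zeros(2 * m), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * m), options=_OPTS)
    return float(res.fun)


def oracle_slr(x: np.ndarray, lam1: float, lam2: float, eps: float = 1e-9) -> float:
    """min ½‖X−XW‖²_F + λ₁‖W‖₁ + λ₂‖W‖_* with diag(W)=0.

    ℓ1 by variable splitting; nuclear norm smoothed as Σ sqrt(σ² + eps²)
    with gradient U diag(σ/sqrt(σ²+eps²)) Vᵀ.
    """
    n = x.shape[1]
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    m = len(off)
    rows = np.array([i for i, _ in off])
    cols = np.array([j for _, j in off])

    def unpack(v):
        w = np.zeros((n, n))
        w[rows, cols] = v[:m] - v[m:]
        return w

    def fun(v):
        w = unpack(v)
        r = x - x @ w
        u, s, vt = np.linalg.svd(w, full_matrices=False)
        f = 0.5 * np.sum(r * r) + lam1 * v.sum() + lam2 * np.sum(np.sqrt(s**2 + eps**2))
        g_nuc = (u * (s / np.sqrt(s**2 + eps**2))) @ vt
        g_w = -(x.T @ r) + lam2 * g_nuc
        g_off = g_w[rows, cols]
        grad = np.concatenate([g_off + lam1, -g_off + lam1])
        return f, grad

    best = np.inf
    for start in (np.zeros(2 * m),):
        res = minimize(fun, start, jac=True, method="L-BFGS-B",
                       bounds=[(0, None)] * (2 * m), options=_OPTS)
        best = min(best, float(res.fun))
    return best


def oracle_gsr(data: list[np.ndarray], lam: float, eps: float = 1e-10) -> float:
    """Σ_i Σ_s ½‖x_i^s − X_i^s w‖² + λ‖W_i‖_{2,1}, ℓ2,1 eps-smoothed."""
    total = 0.0
    n = data[0].shape[1]
    n_s = len(data)
    for i in range(n):
        others = [k for k in range(n) if k != i]
        designs = [x[:, others] for x in data]
        targets = [x[:, i] for x in data]
        p = n - 1

        def fun(v):
            vv = v.reshape(p, n_s)
            f = 0.0
            grad = np.zeros_like(vv)
            for s in range(n_s):
                r = designs[s] @ vv[:, s] - targets[s]
                f += 0.5 * r @ r
                grad[:, s] = designs[s].T @ r
            norms = np.sqrt((vv * vv).sum(axis=1) + eps**2)
            f += lam * norms.sum()
            grad += lam * vv / norms[:, None]
            return f, grad.ravel()

        res = minimize(fun, np.zeros(p * n_s), jac=True, method="L-BFGS-B",
                       options=_OPTS)
        total += float(res.fun)
    return total


def oracle_ssgsr(problems, lam1: float, lam2: float, eps: float = 1e-10) -> float:
    """Full SSGSR objective minimized per ROI by smoothed L-BFGS-B.

    ``problems`` is a list of brainfc GroupProblem objects (designs, targets,
    link_weights, subject_similarity); the objective is evaluated on the
    original (unscaled) variables.
    """
    total = 0.0
    for prob in problems:
        n_s = len(prob.designs)
        p = prob.designs[0].shape[1]
        b = prob.link_weights  # p x S
        sim = prob.subject_similarity

        def fun(v):
            vv = v.reshape(p, n_s)
            f = 0.0
            grad = np.zeros_like(vv)
            for s in range(n_s):
                r = prob.designs[s] @ vv[:, s] - prob.targets[s]
                f += 0.5 * r @ r
                grad[:, s] = prob.designs[s].T @ r
            bw = b * vv
            norms = np.sqrt((bw * bw).sum(axis=1) + eps**2)
            f += lam1 * norms.sum()
            grad += lam1 * (b * bw) / norms[:, None]
            for pp in range(n_s):
                for qq in range(n_s):
                    d = vv[:, pp] - vv[:, qq]
                    f += lam2 * sim[pp, qq] * (d @ d)
                    grad[:, pp] += 2 * lam2 * sim[pp, qq] * d
                    grad[:, qq] -= 2 * lam2 * sim[pp, qq] * d
            return f, grad.ravel()

        res = minimize(fun, np.zeros(p * n_s), jac=True, method="L-BFGS-B",
                       options=_OPTS)
        total += float(res.fun)
    return total


# ------------------------------------------------------- high-order FC, KCC

def brute_thofc(w: np.ndarray) -> np.ndarray:
    """Double-loop correlation-of-correlation with explicit exclusion lists."""
    n = w.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            keep = [k for k in range(n) if k not in (i, j)]
            a = w[i, keep]
            b = w[j, keep]
            out[i, j] = np.corrcoef(a, b)[0, 1]
    return out


def brute_dhofc_network(window_series: np.ndarray, assignments: np.ndarray) -> np.ndarray:
    """Explicit cluster averaging then scalar correlations."""
    k = int(assignments.max())
    means = []
    for c in range(1, k + 1):
        members = window_series[assignments == c]
        means.append(members.mean(axis=0))
    out = np.eye(k)
    for p in range(k):
        for q in range(k):
            if p != q:
                out[p, q] = np.corrcoef(means[p], means[q])[0, 1]
    return out


def brute_kcc(series_stack: np.ndarray) -> float:
    """Textbook rank-sum KCC: W = 12 S / (n² (T³ − T)) on ranked series."""
    n, t = series_stack.shape
    ranks = np.vstack([rankdata(row) for row in series_stack])
    rj = ranks.sum(axis=0)
    s = np.sum((rj - n * (t + 1) / 2) ** 2)
    return float(12 * s / (n**2 * (t**3 - t)))


def mann_whitney_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic with tie handling."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return float(wins / (len(pos) * len(neg)))
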