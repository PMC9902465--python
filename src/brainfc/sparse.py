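"""Sparse-representation functional-connectivity estimators.

Four convex estimators of the N x N coefficient matrix W that reconstructs
each ROI's signal from the others (X ~ XW with diag(W) = 0):

* SR    — per-subject lasso:      min ½‖X − XW‖²_F + λ‖W‖₁
* SLR   — sparse + low-rank:      min ½‖X − XW‖²_F + λ₁‖W‖₁ + λ₂‖W‖_*
* GSR   — group-sparse across subjects: per ROI i,
          min Σ_s ½‖x_i^s − X_i^s w_i^s‖² + λ‖W_i‖_{2,1}
          (the ℓ2,1 norm sums, over candidate ROIs j, the ℓ2 norm of the
          coefficient of j across subjects: rows are zero jointly or not at
          all)
* SSGSR — strength- and similarity-guided GSR: adds LOFC-derived link
          weights b_{i,j}^s = exp(−(w0_{i,j}^s)²) inside the ℓ2,1 norm and a
          between-subject smoothing term λ₂ Σ_{p,q} l_i^{p,q} ‖w_i^p − w_i^q‖²
          with l_i^{p,q} = exp(−‖w0_i^p − w0_i^q‖²).

SR and GSR are solved per column / per ROI with FISTA (soft-threshold or
row-group soft-threshold prox).  SLR uses consensus ADMM with two auxiliary
copies of W (one carrying the ℓ1 prox and the diagonal constraint, one the
singular-value soft-threshold).  SSGSR is reduced to a standard ℓ2,1 prox by
the exact change of variables w̃ = b ⊙ w (valid because b > 0 everywhere),
leaving the similarity term as a smooth quadratic.

Columns are standardized to zero mean and unit ℓ2 norm before solving, which
puts the λ grids on a comparable scale across instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from brainfc.connectivity import FCMatrix, RoiTimeSeries, pearson_fc


@dataclass
class SparseFCParams:
    """Regularization and stopping settings shared by the solvers."""

    lambda1: float = 0.01
    lambda2: float = 0.0
    tol: float = 1e-8
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization weights must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class GroupProblem:
    """Per-ROI stacked design for the group estimators (one ROI i).

    ``designs[s]`` is the T x (N-1) matrix of the other ROIs' signals for
    subject s; ``targets[s]`` the ROI's own signal; ``link_weights`` the
    (N-1) x S matrix of b_{i,j}^s; ``subject_similarity`` the S x S matrix of
    l_i^{p,q}.
    """

    roi_index: int
    designs: list[np.ndarray]
    targets: list[np.ndarray]
    link_weights: np.ndarray
    subject_similarity: np.ndarray


def standardize_columns(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-ℓ2-norm columns."""
    xc = x - x.mean(axis=0)
    norms = np.linalg.norm(xc, axis=0)
    if np.any(norms == 0):
        raise ValueError("constant column cannot be standardized")
    return xc / norms


def soft_threshold(x: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def row_group_soft_threshold(w: np.ndarray, thr: float) -> np.ndarray:
    """Prox of thr * sum of row ℓ2 norms."""
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    scale = np.maximum(1.0 - thr / np.where(norms == 0, 1.0, norms), 0.0)
    return w * scale


def sr_objective(x: np.ndarray, w: np.ndarray, lam: float) -> float:
    return 0.5 * np.linalg.norm(x - x @ w, "fro") ** 2 + lam * np.abs(w).sum()


def slr_objective(x: np.ndarray, w: np.ndarray, lam1: float, lam2: float) -> float:
    return (
        0.5 * np.linalg.norm(x - x @ w, "fro") ** 2
        + lam1 * np.abs(w).sum()
        + lam2 * np.linalg.svd(w, compute_uv=False).sum()
    )


def sr_lambda_max(x: np.ndarray) -> float:
    """Smallest λ at which the SR solution is exactly 0 (per-column lasso)."""
    g = np.abs(x.T @ x)
    np.fill_diagonal(g, 0.0)
    return float(g.max())


def _fista_lasso(a: np.ndarray, b: np.ndarray, lam: float, tol: float,
                 max_iter: int, trace: list | None = None) -> tuple[np.ndarray, bool]:
    """min_w ½‖b − A w‖² + λ‖w‖₁ by FISTA.  Returns (w, converged)."""
    lip = np.linalg.norm(a, 2) ** 2
    if lip == 0:
        return np.zeros(a.shape[1]), True
    w = np.zeros(a.shape[1])
    y = w.copy()
    t_k = 1.0
    ata = a.T @ a
    atb = a.T @ b

    def fval(v):
        r = b - a @ v
        return 0.5 * r @ r + lam * np.abs(v).sum()

    obj_prev = fval(w)
    if trace is not None:
        trace.append(obj_prev)
    quiet = 0
    for _ in range(max_iter):
        grad = ata @ y - atb
        z = soft_threshold(y - grad / lip, lam / lip)
        obj_z = fval(z)
        # monotone FISTA: never let the objective increase
        w_new = z if obj_z <= obj_prev else w
        obj = min(obj_z, obj_prev)
        t_new = (1 + np.sqrt(1 + 4 * t_k**2)) / 2
        y = w_new + (t_k / t_new) * (z - w_new) + ((t_k - 1) / t_new) * (w_new - w)
        w, t_k = w_new, t_new
        if trace is not None:
            trace.append(obj)
        quiet = quiet + 1 if abs(obj_prev - obj) <= tol * max(obj_prev, 1e-12) else 0
        if quiet >= 3:
            return w, True
        obj_prev = obj
    return w, False


def solve_sr(series: RoiTimeSeries, params: SparseFCParams) -> FCMatrix:
    """Per-subject sparse representation (column-separable lasso).

    Column j of W reconstructs ROI j's standardized signal from the other
    ROIs; the diagonal is constrained to 0.  At λ ≥ max_j ‖X₋ⱼᵀ xⱼ‖_∞ the
    solution is exactly the zero matrix.
    """
    x = standardize_columns(series.data)
    n = x.shape[1]
    w = np.zeros((n, n))
    converged = True
    for j in range(n):
        others = [k for k in range(n) if k != j]
        wj, ok = _fista_lasso(x[:, others], x[:, j], params.lambda1,
                              params.tol, params.max_iter)
        w[others, j] = wj
        converged &= ok
    return FCMatrix(w, "SR", roi_labels=list(series.roi_labels),
                    flags={"converged": converged})


def _svt(a: np.ndarray, thr: float) -> np.ndarray:
    """Singular-value soft-threshold (prox of thr·‖·‖_*)."""
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    return (u * np.maximum(s - thr, 0.0)) @ vt


def solve_slr(series: RoiTimeSeries, params: SparseFCParams,
              trace: list | None = None) -> FCMatrix:
    """Sparse low-rank estimator via consensus ADMM with best-iterate tracking.

    Two splitting copies of W carry the two prox steps: Z₁ the ℓ1 prox plus
    the diag(W)=0 projection, Z₂ the singular-value soft-threshold.  The
    W-update solves the ridge system (XᵀX + 2ρI)W = XᵀX + ρ(Z₁−U₁+Z₂−U₂).
    The returned matrix is the best (lowest-objective) Z₁ iterate, so the
    reported objective sequence is non-increasing.  With λ₂ = 0 the solution
    matches :func:`solve_sr`.
    """
    x = standardize_columns(series.data)
    n = x.shape[1]
    lam1, lam2 = params.lambda1, params.lambda2
    rho = 1.0
    xtx = x.T @ x
    chol = np.linalg.cholesky(xtx + 2 * rho * np.eye(n))
    z1 = np.zeros((n, n))
    z2 = np.zeros((n, n))
    u1 = np.zeros((n, n))
    u2 = np.zeros((n, n))
    obj_prev = np.inf
    best_obj = slr_objective(x, z1, lam1, lam2)
    best_z1 = z1.copy()
    if trace is not None:
        trace.append(best_obj)
    converged = False
    for it in range(params.max_iter):
        rhs = xtx + rho * (z1 - u1 + z2 - u2)
        w = np.linalg.solve(chol.T, np.linalg.solve(chol, rhs))
        z1 = soft_threshold(w + u1, lam1 / rho)
        np.fill_diagonal(z1, 0.0)
        z2 = _svt(w + u2, lam2 / rho)
        u1 += w - z1
        u2 += w - z2
        if it % 5 == 4 or it == params.max_iter - 1:
            obj = slr_objective(x, z1, lam1, lam2)
            if obj < best_obj:
                best_obj = obj
                best_z1 = z1.copy()
            if trace is not None:
                trace.append(best_obj)
            prim = max(np.abs(w - z1).max(), np.abs(w - z2).max())
            if abs(obj_prev - obj) <= params.tol * max(abs(obj_prev), 1e-12) \
                    and prim < 1e-6:
                converged = True
                break
            obj_prev = obj
    # Z1 carries the sparsity pattern and the zero diagonal
    return FCMatrix(best_z1, "SLR", roi_labels=list(series.roi_labels),
                    flags={"converged": converged})


def _cohort_standardized(cohort) -> list[np.ndarray]:
    return [standardize_columns(s.data) for s in cohort.subjects]


def gsr_lambda_max(data: list[np.ndarray]) -> float:
    """Smallest λ zeroing the GSR solution: max over (i, j) rows of the
    stacked-gradient row norm ‖(X_i^sᵀ x_i^s)_j across s‖₂ at W = 0."""
    n = data[0].shape[1]
    worst = 0.0
    for i in range(n):
        others = [k for k in range(n) if k != i]
        g = np.vstack([x[:, others].T @ x[:, i] for x in data]).T  # (N-1) x S
        worst = max(worst, float(np.linalg.norm(g, axis=1).max()))
    return worst


def _fista_group(designs, targets, lam, tol, max_iter, weights=None,
                 similarity=None, lam2=0.0, trace=None):
    """Shared FISTA core for GSR (weights/similarity None) and SSGSR.

    Solves, for one ROI, min over the (N-1) x S matrix V:
        Σ_s ½‖b_s − A_s v_s‖² + lam Σ_j ‖row_j(V)‖₂  [+ smooth similarity]
    For SSGSR the caller passes the *scaled* designs (columns divided by b)
    and the similarity quadratic Q(V) = lam2 Σ_{p,q} l_pq ‖D_p v_p − D_q v_q‖²
    with D_s = diag(1/b_s), handled inside the smooth gradient.
    """
    n_s = len(designs)
    p = designs[0].shape[1]
    v = np.zeros((p, n_s))
    y = v.copy()
    atas = [a.T @ a for a in designs]
    atbs = [a.T @ t for a, t in zip(designs, targets)]

    if similarity is not None:
        lap = np.diag(similarity.sum(axis=1)) - similarity  # graph Laplacian
        inv_b = 1.0 / weights  # p x S, scales back to the original variable

        def smooth_grad(vv):
            g = np.column_stack([atas[s] @ vv[:, s] - atbs[s] for s in range(n_s)])
            # d/dV of lam2 * 2 * tr((D∘V) L (D∘V)^T) over ordered pairs:
            # Q(V) = lam2 Σ_{p,q} l_pq ‖u_p − u_q‖², u_s = inv_b[:,s]*v_s
            u = inv_b * vv
            g += 4.0 * lam2 * (u @ lap) * inv_b
            return g

        def smooth_val(vv):
            val = sum(0.5 * np.sum((designs[s] @ vv[:, s] - targets[s]) ** 2)
                      for s in range(n_s))
            u = inv_b * vv
            val += 2.0 * lam2 * float(np.sum(u * (u @ lap)))
            return val

        # Lipschitz bound by power iteration on the full smooth Hessian
        rng = np.random.default_rng(0)
        z = rng.standard_normal((p, n_s))
        z /= np.linalg.norm(z)
        for _ in range(50):
            hz = np.column_stack([atas[s] @ z[:, s] for s in range(n_s)])
            uz = inv_b * z
            hz += 4.0 * lam2 * (uz @ lap) * inv_b
            nz = np.linalg.norm(hz)
            if nz == 0:
                break
            z = hz / nz
        lip = max(nz, 1e-12) * 1.05
    else:
        def smooth_grad(vv):
            return np.column_stack([atas[s] @ vv[:, s] - atbs[s] for s in range(n_s)])

        def smooth_val(vv):
            return sum(0.5 * np.sum((designs[s] @ vv[:, s] - targets[s]) ** 2)
                       for s in range(n_s))

        lip = max(np.linalg.norm(a, 2) ** 2 for a in designs)
        if lip == 0:
            return v, True

    def fval(vv):
        return smooth_val(vv) + lam * np.linalg.norm(vv, axis=1).sum()

    t_k = 1.0
    obj_prev = fval(v)
    if trace is not None:
        trace.append(obj_prev)
    converged = False
    quiet = 0
    for _ in range(max_iter):
        g = smooth_grad(y)
        z = row_group_soft_threshold(y - g / lip, lam / lip)
        obj_z = fval(z)
        v_new = z if obj_z <= obj_prev else v
        obj = min(obj_z, obj_prev)
        t_new = (1 + np.sqrt(1 + 4 * t_k**2)) / 2
        y = v_new + (t_k / t_new) * (z - v_new) + ((t_k - 1) / t_new) * (v_new - v)
        v, t_k = v_new, t_new
        if trace is not None:
            trace.append(obj)
        quiet = quiet + 1 if abs(obj_prev - obj) <= tol * max(abs(obj_prev), 1e-12) else 0
        if quiet >= 3:
            converged = True
            break
        obj_prev = obj
    return v, converged


def solve_gsr(cohort, params: SparseFCParams) -> list[FCMatrix]:
    """Group sparse representation: joint row support across subjects.

    Solved independently per ROI; returns one FC matrix per subject.  With a
    single subject the ℓ2,1 norm degenerates to the ℓ1 norm, so the solution
    coincides with :func:`solve_sr`.
    """
    data = _cohort_standardized(cohort)
    n = data[0].shape[1]
    n_s = len(data)
    ws = [np.zeros((n, n)) for _ in range(n_s)]
    converged = True
    for i in range(n):
        others = [k for k in range(n) if k != i]
        designs = [x[:, others] for x in data]
        targets = [x[:, i] for x in data]
        v, ok = _fista_group(designs, targets, params.lambda1,
                             params.tol, params.max_iter)
        converged &= ok
        for s in range(n_s):
            ws[s][others, i] = v[:, s]
    labels = list(cohort.subjects[0].roi_labels)
    return [FCMatrix(w, "GSR", roi_labels=labels, flags={"converged": converged})
            for w in ws]


def build_group_problem(cohort, roi_index: int,
                        lofc: list[FCMatrix] | None = None) -> GroupProblem:
    """Designs, link weights b = exp(−w0²) and subject similarity
    l^{p,q} = exp(−‖w0_p − w0_q‖²) for one ROI, from per-subject LOFC."""
    if lofc is None:
        lofc = [pearson_fc(s) for s in cohort.subjects]
    data = _cohort_standardized(cohort)
    n = data[0].shape[1]
    others = [k for k in range(n) if k != roi_index]
    designs = [x[:, others] for x in data]
    targets = [x[:, roi_index] for x in data]
    profiles = np.vstack([fc.values[roi_index, others] for fc in lofc])  # S x (N-1)
    link = np.exp(-(profiles.T ** 2))  # (N-1) x S
    d2 = ((profiles[:, None, :] - profiles[None, :, :]) ** 2).sum(axis=2)
    sim = np.exp(-d2)
    return GroupProblem(roi_index, designs, targets, link, sim)


def ssgsr_objective(problems: list[GroupProblem], ws: list[np.ndarray],
                    lam1: float, lam2: float) -> float:
    """Full SSGSR objective summed over ROIs, on the original variables."""
    total = 0.0
    n = ws[0].shape[0]
    for prob in problems:
        i = prob.roi_index
        others = [k for k in range(n) if k != i]
        v = np.column_stack([ws[s][others, i] for s in range(len(ws))])
        for s in range(len(ws)):
            r = prob.targets[s] - prob.designs[s] @ v[:, s]
            total += 0.5 * r @ r
        total += lam1 * np.linalg.norm(prob.link_weights * v, axis=1).sum()
        diff2 = ((v[:, :, None] - v[:, None, :]) ** 2).sum(axis=0)
        total += lam2 * float((prob.subject_similarity * diff2).sum())
    return total


def solve_ssgsr(cohort, params: SparseFCParams,
                lofc: list[FCMatrix] | None = None) -> list[FCMatrix]:
    """Strength- and similarity-guided GSR.

    The weighted ℓ2,1 term is handled by the exact substitution ṽ = b ⊙ v
    (b > 0 always), which rescales the design columns by 1/b and turns the
    penalty into a standard row-group norm; the similarity term stays a
    smooth quadratic in ṽ.
    """
    data = _cohort_standardized(cohort)
    n = data[0].shape[1]
    n_s = len(data)
    ws = [np.zeros((n, n)) for _ in range(n_s)]
    converged = True
    for i in range(n):
        prob = build_group_problem(cohort, i, lofc=lofc)
        others = [k for k in range(n) if k != i]
        b = prob.link_weights  # (N-1) x S
        scaled = [prob.designs[s] / b[:, s] for s in range(n_s)]
        v_tilde, ok = _fista_group(
            scaled, prob.targets, params.lambda1, params.tol, params.max_iter,
            weights=b, similarity=prob.subject_similarity, lam2=params.lambda2,
        )
        converged &= ok
        v = v_tilde / b
        for s in range(n_s):
            ws[s][others, i] = v[:, s]
    labels = list(cohort.subjects[0].roi_labels)
    return [FCMatrix(w, "SSGSR", roi_labels=labels, flags={"converged": converged})
            for w in ws]


def symmetrize(fc: FCMatrix) -> FCMatrix:
    """(W + Wᵀ)/2 — the undirected network the biomarker tables report."""
    return FCMatrix((fc.values + fc.values.T) / 2, fc.method_tag,
                    roi_labels=list(fc.roi_labels), flags=dict(fc.flags))
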