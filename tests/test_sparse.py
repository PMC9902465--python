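"""Sparse-representation solvers against analytic limits and a generic oracle."""

import numpy as np
import pytest

from brainfc.connectivity import RoiTimeSeries
from brainfc.sparse import (
    SparseFCParams,
    _fista_group,
    _fista_lasso,
    build_group_problem,
    gsr_lambda_max,
    slr_objective,
    solve_gsr,
    solve_slr,
    solve_sr,
    solve_ssgsr,
    sr_lambda_max,
    sr_objective,
    ssgsr_objective,
    standardize_columns,
    symmetrize,
)
from conftest import mini_cohort
from oracles import oracle_gsr, oracle_slr, oracle_sr, oracle_ssgsr

TIGHT = SparseFCParams(lambda1=0.01, tol=1e-11, max_iter=20000)


def _random_ts(seed, t=30, n=5):
    return RoiTimeSeries(np.random.default_rng(seed).standard_normal((t, n)))


class TestSR:
    def test_lambda_max_zeroes_solution_exactly(self):
        ts = _random_ts(0)
        lam = sr_lambda_max(standardize_columns(ts.data))
        fc = solve_sr(ts, SparseFCParams(lambda1=lam * 1.0001))
        assert np.all(fc.values == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_matches_convex_oracle(self, seed):
        ts = _random_ts(seed)
        params = SparseFCParams(lambda1=0.01, tol=1e-11, max_iter=20000)
        fc = solve_sr(ts, params)
        xs = standardize_columns(ts.data)
        mine = sr_objective(xs, fc.values, 0.01)
        orc = oracle_sr(xs, 0.01)
        assert abs(mine - orc) / orc < 1e-4

    def test_duplicate_roi_concentrates_mass(self):
        rng = np.random.default_rng(42)
        base = rng.standard_normal((60, 4))
        x = np.column_stack([base, base[:, 0] + 1e-9 * rng.standard_normal(60)])
        fc = solve_sr(RoiTimeSeries(x), SparseFCParams(lambda1=0.05, tol=1e-11,
                                                       max_iter=20000))
        col = np.abs(fc.values[:, 4])
        assert col[0] == col.max() and col[0] > 0.5 * col.sum()

    def test_sparsity_nonincreasing_in_lambda(self):
        ts = _random_ts(7, t=40, n=6)
        nnz = []
        for lam in [0.005, 0.01, 0.02, 0.05, 0.1, 0.3]:
            fc = solve_sr(ts, SparseFCParams(lambda1=lam, tol=1e-11, max_iter=20000))
            nnz.append(int(np.count_nonzero(fc.values)))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_objective_trace_monotone(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((30, 6))
        trace = []
        _fista_lasso(a, rng.standard_normal(30), 0.05, 1e-10, 2000, trace=trace)
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-12)


class TestSLR:
    def test_lambda2_zero_reduces_to_sr(self):
        ts = _random_ts(1)
        xs = standardize_columns(ts.data)
        fc_slr = solve_slr(ts, SparseFCParams(lambda1=0.03, lambda2=0.0,
                                              tol=1e-11, max_iter=10000))
        fc_sr = solve_sr(ts, SparseFCParams(lambda1=0.03, tol=1e-11, max_iter=20000))
        o1 = sr_objective(xs, fc_slr.values, 0.03)
        o2 = sr_objective(xs, fc_sr.values, 0.03)
        assert abs(o1 - o2) / o2 < 1e-6

    def test_large_penalties_zero_solution(self):
        ts = _random_ts(2)
        lam = sr_lambda_max(standardize_columns(ts.data)) * 2
        fc = solve_slr(ts, SparseFCParams(lambda1=lam, lambda2=lam,
                                          tol=1e-10, max_iter=5000))
        assert np.max(np.abs(fc.values)) < 1e-10

    @pytest.mark.parametrize("seed", range(3))
    def test_objective_matches_convex_oracle(self, seed):
        ts = _random_ts(seed + 10)
        params = SparseFCParams(lambda1=0.05, lambda2=0.08, tol=1e-11, max_iter=10000)
        fc = solve_slr(ts, params)
        xs = standardize_columns(ts.data)
        mine = slr_objective(xs, fc.values, 0.05, 0.08)
        orc = oracle_slr(xs, 0.05, 0.08)
        assert abs(mine - orc) / orc < 1e-4

    def test_trace_norm_shrinks_with_lambda2(self):
        ts = _random_ts(20)
        f0 = solve_slr(ts, SparseFCParams(lambda1=0.05, lambda2=0.0,
                                          tol=1e-11, max_iter=10000))
        f1 = solve_slr(ts, SparseFCParams(lambda1=0.05, lambda2=0.08,
                                          tol=1e-11, max_iter=10000))
        nuc0 = np.linalg.svd(f0.values, compute_uv=False).sum()
        nuc1 = np.linalg.svd(f1.values, compute_uv=False).sum()
        assert nuc1 <= nuc0 + 1e-8

    def test_objective_trace_monotone(self):
        ts = _random_ts(21)
        trace = []
        solve_slr(ts, SparseFCParams(lambda1=0.05, lambda2=0.08,
                                     tol=1e-11, max_iter=5000), trace=trace)
        assert np.all(np.diff(trace) <= 1e-12)


class TestGSR:
    def test_group_lambda_max_zeroes_solution(self):
        co = mini_cohort(0)
        data = [standardize_columns(s.data) for s in co.subjects]
        lam = gsr_lambda_max(data)
        ws = solve_gsr(co, SparseFCParams(lambda1=lam * 1.0001))
        assert all(np.all(w.values == 0.0) for w in ws)

    def test_single_subject_reduces_to_sr(self):
        co = mini_cohort(5, n_subjects=1)
        ts = co.subjects[0]
        xs = standardize_columns(ts.data)
        w_g = solve_gsr(co, TIGHT)[0]
        w_s = solve_sr(ts, TIGHT)
        o_g = sr_objective(xs, w_g.values, 0.01)
        o_s = sr_objective(xs, w_s.values, 0.01)
        assert abs(o_g - o_s) / o_s < 1e-6

    @pytest.mark.parametrize("seed", range(3))
    def test_objective_matches_oracle_and_joint_support(self, seed):
        co = mini_cohort(seed, n_subjects=3)
        ws = solve_gsr(co, TIGHT)
        data = [standardize_columns(s.data) for s in co.subjects]
        n = 5
        mine = 0.0
        for i in range(n):
            others = [k for k in range(n) if k != i]
            v = np.column_stack([w.values[others, i] for w in ws])
            for s in range(3):
                r = data[s][:, i] - data[s][:, others] @ v[:, s]
                mine += 0.5 * r @ r
            mine += 0.01 * np.linalg.norm(v, axis=1).sum()
            nz = v != 0
            assert np.array_equal(nz.any(axis=1), nz.all(axis=1))
        orc = oracle_gsr(data, 0.01)
        assert abs(mine - orc) / orc < 1e-4


class TestSSGSR:
    def test_build_group_problem_printed_formulas(self):
        co = mini_cohort(1)
        prob = build_group_problem(co, 0)
        assert np.all(prob.link_weights > 0) and np.all(prob.link_weights <= 1)
        assert np.allclose(prob.subject_similarity, prob.subject_similarity.T)
        assert np.allclose(np.diag(prob.subject_similarity), 1.0)
        # b = exp(-w0^2) spot values
        assert np.exp(-0.0**2) == 1.0
        assert np.exp(-1.0**2) == pytest.approx(0.36787944117, abs=1e-10)

    def test_identical_lofc_gives_unit_similarity(self):
        from brainfc.connectivity import FCMatrix

        co = mini_cohort(2, n_subjects=2)
        lofc_vals = np.full((5, 5), 0.3)
        np.fill_diagonal(lofc_vals, 1.0)
        lofc = [FCMatrix(lofc_vals, "PC") for _ in range(2)]
        prob = build_group_problem(co, 0, lofc=lofc)
        assert np.allclose(prob.subject_similarity, 1.0)

    def test_large_lambda2_forces_consensus(self):
        co = mini_cohort(3, n_subjects=3)
        params = SparseFCParams(lambda1=0.01, lambda2=2000.0, tol=1e-13,
                                max_iter=100000)
        ws = solve_ssgsr(co, params)
        for pair in [(0, 1), (0, 2)]:
            diff = np.abs(ws[pair[0]].values - ws[pair[1]].values).max()
            assert diff < 1e-4

    def test_constant_lofc_matches_uniform_laplacian_oracle(self):
        from brainfc.connectivity import FCMatrix

        co = mini_cohort(4, n_subjects=3)
        lofc_vals = np.full((5, 5), 0.5)
        np.fill_diagonal(lofc_vals, 1.0)
        lofc = [FCMatrix(lofc_vals, "PC") for _ in range(3)]
        params = SparseFCParams(lambda1=0.06, lambda2=0.01, tol=1e-12,
                                max_iter=30000)
        ws = solve_ssgsr(co, params, lofc=lofc)
        probs = [build_group_problem(co, i, lofc=lofc) for i in range(5)]
        assert np.allclose(probs[0].subject_similarity, 1.0)
        mine = ssgsr_objective(probs, [w.values for w in ws], 0.06, 0.01)
        orc = oracle_ssgsr(probs, 0.06, 0.01)
        assert abs(mine - orc) / orc < 1e-4

    @pytest.mark.parametrize("seed", range(3))
    def test_objective_matches_convex_oracle(self, seed):
        co = mini_cohort(seed + 30, n_subjects=3)
        params = SparseFCParams(lambda1=0.06, lambda2=0.01, tol=1e-12,
                                max_iter=30000)
        ws = solve_ssgsr(co, params)
        probs = [build_group_problem(co, i) for i in range(5)]
        mine = ssgsr_objective(probs, [w.values for w in ws], 0.06, 0.01)
        orc = oracle_ssgsr(probs, 0.06, 0.01)
        assert abs(mine - orc) / orc < 1e-4


class TestSymmetrize:
    def test_symmetric_unchanged_and_idempotent(self):
        from brainfc.connectivity import FCMatrix

        rng = np.random.default_rng(6)
        w = rng.standard_normal((4, 4))
        fc = FCMatrix(w, "SR")
        s1 = symmetrize(fc)
        s2 = symmetrize(s1)
        np.testing.assert_allclose(s1.values, (w + w.T) / 2, atol=1e-15)
        np.testing.assert_array_equal(s1.values, s2.values)
        assert s1.method_tag == "SR"

    def test_halves_asymmetric_entries(self):
        from brainfc.connectivity import FCMatrix

        w = np.zeros((3, 3))
        w[0, 1] = 0.4
        s = symmetrize(FCMatrix(w, "SR"))
        assert s.values[0, 1] == s.values[1, 0] == pytest.approx(0.2)
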