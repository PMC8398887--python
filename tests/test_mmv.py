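"""MMV solvers: greedy selection, reweighted minimum norm, Pareto root finding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgcs.mmv import m_focuss, m_omp, spgl1_mmv, support_of

from conftest import sparse_instance, wrap_matrix


class TestSupportOf:
    def test_zero_matrix_empty_support(self):
        assert support_of(np.zeros((5, 3))).size == 0

    def test_literal_nonzeros_at_tol_zero(self):
        A = np.zeros((4, 2))
        A[1, 0] = 1e-30
        assert support_of(A).tolist() == [1]

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 100), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_larger_tol_gives_subset(self, seed, t1, t2):
        A = np.random.default_rng(seed).standard_normal((8, 3))
        lo, hi = sorted((t1, t2))
        assert set(support_of(A, hi)) <= set(support_of(A, lo))


class TestMOMP:
    def test_orthonormal_atoms_act_as_coordinate_selection(self):
        d = wrap_matrix(np.eye(4))
        X = np.array([0.0, 3.0, 0.0, 1.0]).reshape(-1, 1)
        sol = m_omp(X, d, max_iter=2)
        assert sol.support_history[0].tolist() == [1]
        assert sol.support_history[1].tolist() == [1, 3]
        assert sol.residual_history[-1] == pytest.approx(0.0, abs=1e-12)

    def test_orthonormal_k_sparse_terminates_in_k_steps(self):
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.standard_normal((12, 12)))
        d = wrap_matrix(Q)
        rows = [2, 5, 9]
        B = rng.standard_normal((3, 4))
        X = Q[:, rows] @ B
        sol = m_omp(X, d, r_th=1e-10)
        assert sol.iterations_run == 3
        assert sorted(sol.support_history[-1].tolist()) == rows
        assert sol.residual_history[-1] < 1e-10

    def test_residual_history_nonincreasing(self):
        rng = np.random.default_rng(2)
        d = wrap_matrix(rng.standard_normal((16, 30)))
        X = rng.standard_normal((16, 3))
        sol = m_omp(X, d, max_iter=10)
        assert np.all(np.diff(sol.residual_history) <= 1e-12)

    def test_zero_signal_returns_empty_solution(self):
        d = wrap_matrix(np.eye(4))
        sol = m_omp(np.zeros((4, 2)), d)
        assert sol.iterations_run == 0
        assert np.all(sol.A == 0)
        assert sol.support.size == 0

    def test_matches_exhaustive_two_subset_oracle(self, psi1_64):
        hits = 0
        for seed in range(10):
            X, gen, _ = sparse_instance(seed, psi1_64, K=2, F=3, snr_db=None)
            sol = m_omp(X, psi1_64, max_iter=2)
            # brute force: the 2-subset with minimal least-squares residual
            P = psi1_64.n_columns
            best, best_r = None, np.inf
            for i in range(P):
                for j in range(i + 1, P):
                    A, *_ = np.linalg.lstsq(psi1_64.matrix[:, [i, j]], X, rcond=None)
                    r = np.linalg.norm(X - psi1_64.matrix[:, [i, j]] @ A)
                    if r < best_r:
                        best, best_r = {i, j}, r
            assert best == set(gen.tolist())
            if set(sol.support_history[-1].tolist()) == best:
                hits += 1
        assert hits == 10

    def test_column_permutation_of_x_permutes_coefficients(self, psi1_64):
        X, _, rng = sparse_instance(3, psi1_64, K=3, F=4)
        perm = rng.permutation(4)
        a = m_omp(X, psi1_64, max_iter=5)
        b = m_omp(X[:, perm], psi1_64, max_iter=5)
        assert np.allclose(a.A[:, perm], b.A)
        assert np.array_equal(a.support, b.support)


class TestMFocuss:
    def test_single_unweighted_step_is_min_norm_solution(self):
        rng = np.random.default_rng(4)
        d = wrap_matrix(rng.standard_normal((8, 20)))
        X = rng.standard_normal((8, 3))
        sol = m_focuss(X, d, lam=0.0, p_exp=2.0, max_iter=1, prune=False)
        expected = np.linalg.pinv(d.matrix) @ X
        assert np.allclose(sol.A, expected, atol=1e-8)

    def test_retained_set_only_shrinks(self, psi1_64):
        X, _, _ = sparse_instance(5, psi1_64, K=3, F=6)
        sol = m_focuss(X, psi1_64, max_iter=60)
        sizes = [s.size for s in sol.support_history]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_objective_nonincreasing_without_pruning(self, psi1_64):
        X, _, _ = sparse_instance(6, psi1_64, K=3, F=6)
        sol = m_focuss(X, psi1_64, max_iter=120, prune=False)
        assert np.all(np.diff(sol.residual_history) <= 1e-9)

    def test_recovers_generating_atoms(self, psi1_64):
        X, gen, _ = sparse_instance(7, psi1_64, K=3, F=6)
        sol = m_focuss(X, psi1_64, lam=2.5e-4, max_iter=200)
        assert set(gen.tolist()) <= set(sol.support_history[-1].tolist())

    def test_column_permutation_equivariance(self, psi1_64):
        X, _, rng = sparse_instance(8, psi1_64, K=3, F=5)
        perm = rng.permutation(5)
        a = m_focuss(X, psi1_64, max_iter=30)
        b = m_focuss(X[:, perm], psi1_64, max_iter=30)
        assert np.allclose(a.A[:, perm], b.A, atol=1e-8)


class TestSPGL1:
    def test_zero_solution_when_sigma_exceeds_signal_norm(self, psi1_64):
        X, _, _ = sparse_instance(9, psi1_64, K=3, F=4)
        sol = spgl1_mmv(X, psi1_64, sigma_star=2 * np.linalg.norm(X))
        assert np.all(sol.A == 0)
        assert sol.support.size == 0
        assert sol.converged

    def test_feasibility_at_convergence(self, psi1_64):
        for seed in range(5):
            X, gen, _ = sparse_instance(20 + seed, psi1_64, K=3, F=4)
            sigma = 0.1 * np.linalg.norm(X)
            sol = spgl1_mmv(X, psi1_64, sigma_star=sigma)
            assert sol.converged
            resid = np.linalg.norm(psi1_64.matrix @ sol.A - X)
            assert resid <= sigma + 1e-6 * np.linalg.norm(X)
            assert set(gen.tolist()) <= set(support_of(sol, 1e-4).tolist())

    def test_sigma_history_nonincreasing(self, psi1_64):
        X, _, _ = sparse_instance(30, psi1_64, K=4, F=4)
        sol = spgl1_mmv(X, psi1_64, sigma_star=0.05 * np.linalg.norm(X))
        assert np.all(np.diff(sol.residual_history) <= 1e-9)

    def test_unreachable_sigma_reports_best_reached(self, psi1_64):
        X, _, _ = sparse_instance(31, psi1_64, K=3, F=4)
        sol = spgl1_mmv(X, psi1_64, sigma_star=1e-12, max_iter=2)
        assert not sol.converged
        assert sol.info["sigma_reached"] > 1e-12
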