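import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpprop.problems import SolverOptions, assemble_dense, generate_synthetic_problem
from cpprop.reference import direct_inversion_solve
from cpprop.solver import (CI, GERADE, ORBITAL, UNGERADE, PairedVector,
                           Preconditioner, TrialSubspace, apply_hessian_metric,
                           assemble_reduced, back_project_and_residuals,
                           collapse_subspace, precondition, run_cpp,
                           schedule_frequencies, solve_reduced,
                           split_gerade_ungerade)
from cpprop.units import ev_to_au

from conftest import one_parameter_problem

DIP = "electric-dipole-length"


class TestSplit:
    def test_symmetric_input_has_no_ungerade_part(self):
        z = np.arange(5.0)
        g, u = split_gerade_ungerade(np.concatenate([z, z]))
        assert np.array_equal(g, z) and np.all(u == 0)

    def test_antisymmetric_input_has_no_gerade_part(self):
        z = np.arange(5.0) + 1
        g, u = split_gerade_ungerade(np.concatenate([z, -z]))
        assert np.all(g == 0) and np.array_equal(u, z)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
    def test_roundtrip_exact(self, vals):
        if len(vals) % 2:
            vals = vals + [0.0]
        v = np.asarray(vals)
        g, u = split_gerade_ungerade(v)
        err = np.abs(np.concatenate([g + u, g - u]) - v)
        assert np.max(err) <= 1e-15 * max(np.max(np.abs(v)), 1e-300)

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            split_gerade_ungerade(np.ones(5))


class TestHessianMetricProducts:
    def test_one_parameter_gerade(self):
        p = one_parameter_problem(a=0.4, b=0.1)
        v = PairedVector(np.array([2.0]), GERADE, ORBITAL)
        sigma, tau = apply_hessian_metric(p, v)
        assert sigma.symmetry == GERADE and tau.symmetry == UNGERADE
        assert sigma.half[0] == pytest.approx(0.5 * 2.0)   # (A+B) z
        assert tau.half[0] == pytest.approx(2.0)           # (Sigma +/- Delta) z, Delta=0

    def test_tda_uses_bare_blocks(self):
        p = one_parameter_problem(a=0.4, b=0.1)
        v = PairedVector(np.array([2.0]), GERADE, ORBITAL)
        sigma, tau = apply_hessian_metric(p, v, tda=True)
        assert sigma.half[0] == pytest.approx(0.4 * 2.0)   # A z
        assert tau.half[0] == pytest.approx(2.0)           # Sigma z
        assert sigma.symmetry == GERADE and tau.symmetry == UNGERADE

    @pytest.mark.parametrize("symmetry", [GERADE, UNGERADE])
    def test_matches_dense_full_space_products(self, symmetry):
        """sigma/tau equal E2/S2 acting on the lifted full-space vector."""
        p = generate_synthetic_problem(40, 20, seed=8)
        E2, S2 = assemble_dense(p)
        rng = np.random.default_rng(0)
        N = p.half_dim
        sgn = 1.0 if symmetry == GERADE else -1.0
        for _ in range(10):
            z = rng.standard_normal(N)
            v = PairedVector(z, symmetry, ORBITAL)
            sigma, tau = apply_hessian_metric(p, v)
            full = np.concatenate([z, sgn * z])
            sig_full = E2 @ full
            tau_full = S2 @ full
            # Hessian preserves the symmetry, metric flips it
            assert np.allclose(sig_full[:N], sgn * sig_full[N:], atol=1e-12)
            assert np.allclose(tau_full[:N], -sgn * tau_full[N:], atol=1e-12)
            assert np.max(np.abs(sigma.half - sig_full[:N])) <= 1e-12 * max(1, np.abs(sig_full).max())
            assert np.max(np.abs(tau.half - tau_full[:N])) <= 1e-12 * max(1, np.abs(tau_full).max())
            assert sigma.symmetry == symmetry
            assert tau.symmetry == (UNGERADE if symmetry == GERADE else GERADE)


class TestSubspace:
    def _subspace(self, problem):
        return TrialSubspace(problem, lindep_threshold=1e-8)

    def test_duplicate_rejected(self, small_problem):
        sub = self._subspace(small_problem)
        v = np.zeros(small_problem.half_dim)
        v[0] = 1.0
        assert sub.extend([PairedVector(v, GERADE, ORBITAL)]) == 1
        assert sub.extend([PairedVector(2.5 * v, GERADE, ORBITAL)]) == 0

    def test_orthogonal_complement_admitted(self, small_problem):
        sub = self._subspace(small_problem)
        v1 = np.zeros(small_problem.half_dim); v1[0] = 1.0
        v2 = np.zeros(small_problem.half_dim); v2[1] = 1.0
        sub.extend([PairedVector(v1, GERADE, ORBITAL)])
        assert sub.extend([PairedVector(v2, GERADE, ORBITAL)]) == 1
        B = sub.basis[GERADE]
        assert np.allclose(B @ B.T, np.eye(2), atol=1e-14)

    def test_random_candidates_give_identity_gram(self, small_problem):
        sub = self._subspace(small_problem)
        rng = np.random.default_rng(1)
        n_orb = small_problem.n_orb
        cands = []
        for _ in range(5):
            v = np.zeros(small_problem.half_dim)
            v[:n_orb] = rng.standard_normal(n_orb)
            cands.append(PairedVector(v, UNGERADE, ORBITAL))
        assert sub.extend(cands) == 5
        B = sub.basis[UNGERADE]
        assert np.max(np.abs(B @ B.T - np.eye(5))) <= 1e-10

    def test_incremental_reduced_matches_rebuild(self, medium_problem):
        opts = SolverOptions(residual_threshold=1e-5)
        sol = run_cpp(medium_problem, [6.0, 11.0], opts)
        sub = sol._subspace
        inc, scratch = sub.reduced(), sub.reduced_from_scratch()
        for a, b in ((inc.E_gg, scratch.E_gg), (inc.E_uu, scratch.E_uu),
                     (inc.S_gu, scratch.S_gu)):
            assert np.max(np.abs(a - b)) <= 1e-12 * max(1.0, np.abs(b).max())

    def test_gerade_ungerade_cross_blocks_vanish(self, small_problem):
        """Full-space E2 cross products between g and u vectors are zero."""
        E2, S2 = assemble_dense(small_problem)
        rng = np.random.default_rng(2)
        N = small_problem.half_dim
        for _ in range(5):
            zg, zu = rng.standard_normal(N), rng.standard_normal(N)
            fg = np.concatenate([zg, zg])
            fu = np.concatenate([zu, -zu])
            assert abs(fg @ (E2 @ fu)) <= 1e-10 * np.abs(E2).max() * N
            assert abs(fg @ (S2 @ fg)) <= 1e-10 * np.abs(S2).max() * N


class TestReducedSolve:
    def test_full_canonical_basis_reproduces_direct_inversion(self, small_problem):
        p = small_problem
        N, n_orb = p.half_dim, p.n_orb
        sub = TrialSubspace(p)
        for sym in (GERADE, UNGERADE):
            for i in range(N):
                v = np.zeros(N); v[i] = 1.0
                sub.extend([PairedVector(v, sym, ORBITAL if i < n_orb else CI)])
        g = p.gradient(DIP, "x")
        sub.register_gradient(g)
        omega_au, gamma_au = ev_to_au(9.0), ev_to_au(0.124)
        M, (sl_gR, sl_uR, sl_uI, sl_gI) = assemble_reduced(sub, omega_au, gamma_au)
        rhs = np.zeros(M.shape[0])
        p_g, p_u = sub.gradient_rhs(g)
        rhs[sl_gR], rhs[sl_uI] = p_g, p_u
        c = solve_reduced(M, rhs[:, None])[:, 0]
        coeffs = (c[sl_gR], c[sl_uR], c[sl_uI], c[sl_gI])
        X, _, total = back_project_and_residuals(sub, coeffs, g, omega_au, gamma_au)
        assert total <= 1e-10 * g.norm_full()
        X_full = (X[0] + X[1]) + 1j * (X[3] + X[2])
        X_ref = direct_inversion_solve(p, 9.0, 0.124, g)
        assert np.allclose(np.concatenate([X_full, (X[0] - X[1]) + 1j * (X[3] - X[2])]),
                           X_ref, atol=1e-9 * np.abs(X_ref).max())

    def test_single_gerade_vector_decouples(self, small_problem):
        sub = TrialSubspace(small_problem)
        v = np.zeros(small_problem.half_dim); v[0] = 1.0
        sub.extend([PairedVector(v, GERADE, ORBITAL)])
        r = sub.reduced()
        assert r.E_uu.shape == (0, 0) and r.S_gu.shape == (1, 0)
        M, _ = assemble_reduced(sub, 0.3, 0.01)
        # block diagonal: the single gerade R and I coefficients decouple
        assert M.shape == (2, 2) and M[0, 1] == 0 and M[1, 0] == 0

    def test_real_limit_no_imaginary_coefficients(self, small_problem):
        """gamma -> 0 with a real gradient leaves X^I exactly zero."""
        sub = TrialSubspace(small_problem)
        rng = np.random.default_rng(3)
        N, n_orb = small_problem.half_dim, small_problem.n_orb
        for sym in (GERADE, UNGERADE):
            for blk, sl in ((ORBITAL, slice(0, n_orb)), (CI, slice(n_orb, N))):
                v = np.zeros(N); v[sl] = rng.standard_normal(sl.stop - sl.start)
                sub.extend([PairedVector(v, sym, blk)])
        g = small_problem.gradient(DIP, "x")
        sub.register_gradient(g)
        M, (sl_gR, sl_uR, sl_uI, sl_gI) = assemble_reduced(sub, ev_to_au(3.0), 0.0)
        rhs = np.zeros(M.shape[0])
        p_g, p_u = sub.gradient_rhs(g)
        rhs[sl_gR], rhs[sl_uI] = p_g, p_u  # p_u = 0 for a real gradient
        c = solve_reduced(M, rhs[:, None])[:, 0]
        assert np.all(c[sl_uI] == 0) and np.all(c[sl_gI] == 0)

    def test_scalar_reduced_closed_form(self):
        M = np.array([[2.5]])
        c = solve_reduced(M, np.array([[1.25]]))
        assert c[0, 0] == pytest.approx(0.5)

    def test_random_plugback_residual(self):
        rng = np.random.default_rng(4)
        M = rng.standard_normal((12, 12)) + 6 * np.eye(12)
        rhs = rng.standard_normal((12, 2))
        c = solve_reduced(M, rhs)
        assert np.linalg.norm(M @ c - rhs) <= 1e-12 * np.linalg.norm(rhs)

    def test_zero_gradient_zero_solution(self, small_problem):
        from cpprop.problems import OperatorGradient
        sub = TrialSubspace(small_problem)
        v = np.zeros(small_problem.half_dim); v[0] = 1.0
        sub.extend([PairedVector(v, GERADE, ORBITAL)])
        g0 = OperatorGradient("custom", "x", np.zeros(small_problem.half_dim),
                              np.zeros(small_problem.half_dim))
        coeffs = (np.zeros(1), np.zeros(0), np.zeros(0), np.zeros(1))
        X, res, total = back_project_and_residuals(sub, coeffs, g0, 0.3, 0.005)
        assert total == 0.0 and all(np.all(x == 0) for x in X)


class TestPreconditioner:
    def test_exact_on_diagonal_problem_any_frequency(self, diagonal_problem):
        for omega, gamma in [(3.0, 0.124), (9.5, 0.5), (14.0, 0.01)]:
            sol = run_cpp(diagonal_problem, [omega],
                          SolverOptions(gamma=gamma, residual_threshold=1e-8))
            assert sol.converged and sol.n_iterations == 1

    def test_real_limit_gives_no_imaginary_candidates(self, small_problem):
        pre = Preconditioner.from_problem(small_problem)
        rng = np.random.default_rng(5)
        N = small_problem.half_dim
        res = (rng.standard_normal(N), rng.standard_normal(N), np.zeros(N), np.zeros(N))
        cands = precondition(res, pre, ev_to_au(3.0), 0.0, small_problem)
        # residual components uI, gI are zero => no imaginary candidates survive
        assert len(cands) == 4
        tags = {(c.symmetry, c.block) for c in cands}
        assert tags == {(GERADE, ORBITAL), (GERADE, CI), (UNGERADE, ORBITAL), (UNGERADE, CI)}

    def test_beats_identity_preconditioner(self):
        """Across 10 seeds, the diagonal-model inverse reaches a lower total
        residual than raw-residual expansion after the same iteration count."""
        wins = 0
        for seed in range(10):
            p = generate_synthetic_problem(60, 15, seed=seed, spectral_range=(2.0, 30.0))
            opts = SolverOptions(residual_threshold=1e-14, max_iterations=3)
            aops = p.gradients_for(DIP)[:1]
            sol_pre = run_cpp(p, [5.0], opts, a_operators=aops, b_operators=aops)
            ident = Preconditioner(eg=np.ones(p.half_dim), eu=np.ones(p.half_dim),
                                   s=np.zeros(p.half_dim))
            sol_idn = run_cpp(p, [5.0], opts, a_operators=aops, b_operators=aops,
                              preconditioner=ident)
            r_pre = sol_pre.equations[(DIP, "x", 0)].residual_history[-1]
            r_idn = sol_idn.equations[(DIP, "x", 0)].residual_history[-1]
            wins += r_pre < r_idn
        assert wins == 10


class TestCollapse:
    def _filled_subspace(self, problem, n_orb_vecs):
        sub = TrialSubspace(problem)
        rng = np.random.default_rng(6)
        for _ in range(n_orb_vecs):
            v = np.zeros(problem.half_dim)
            v[:problem.n_orb] = rng.standard_normal(problem.n_orb)
            sub.extend([PairedVector(v, GERADE, ORBITAL)])
        return sub

    def test_collapse_to_solution_rank(self, small_problem):
        sub = self._filled_subspace(small_problem, 10)
        rng = np.random.default_rng(7)
        N = small_problem.half_dim
        basis = rng.standard_normal((3, N))  # rank-3 solution span
        sols = []
        for _ in range(4):
            mix = rng.standard_normal(3) @ basis
            halves = (mix, np.zeros(N), np.zeros(N), rng.standard_normal(3) @ basis)
            sols.append(halves)
        new = collapse_subspace(sub, sols, ORBITAL, svd_threshold=1e-10)
        assert new.pool_sizes()[(GERADE, ORBITAL)] == 3

    def test_duplicate_solutions_do_not_raise_rank(self, small_problem):
        sub = self._filled_subspace(small_problem, 8)
        rng = np.random.default_rng(8)
        N = small_problem.half_dim
        halves = (rng.standard_normal(N), np.zeros(N), np.zeros(N), np.zeros(N))
        new = collapse_subspace(sub, [halves, halves, halves], ORBITAL, 1e-10)
        assert new.pool_sizes()[(GERADE, ORBITAL)] == 1


class TestScheduling:
    def test_initial_count_covers_grid(self):
        opts = SolverOptions(dynamic_enabled=True, dynamic_initial_count=10)
        assert np.array_equal(schedule_frequencies(6, opts), np.arange(6))

    def test_two_endpoints_activate_inward(self):
        from cpprop.solver import activate_neighbors
        active = {0, 7}
        order = []
        while len(active) < 8:
            fresh = activate_neighbors(active, 8)
            order.append(sorted(fresh))
            active |= fresh
        assert order == [[1, 6], [2, 5], [3, 4]]
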