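"""Maximum-entropy programs: oracles, constraints and penalty behavior.

The key oracle is classical: on any positive covariance sequence, the
unpenalized maximum-entropy problem is equivalent to the Yule-Walker fit
of a VAR(p) model, so its block traces must reproduce the Yule-Walker
ISDM coefficients.  The Yule-Walker solve below is an independent
closed-form route (block normal equations), not the conic solver.
"""

import numpy as np
import pytest

from vargraph.maxent import (SolverError, solve_me1, solve_me2, solve_me3,
                             solve_sparse_lowrank, sparsity_promoter)
from vargraph.specfact import spectral_factorize
from vargraph.varsim import (CovarianceSequence, SparsityPattern,
                             VARModel, isdm_from_var, sample_covariances,
                             simulate_var, theoretical_covariances)


TIGHT = dict(gap_tol=1e-8)


def yule_walker_isdm(cov: CovarianceSequence):
    """Closed-form Yule-Walker fit -> ISDM coefficients (test oracle)."""
    p, K = cov.q, cov.dim
    G = np.block([[cov.lag(j - i) for j in range(1, p + 1)]
                  for i in range(1, p + 1)])
    g = np.hstack([cov.lag(i) for i in range(1, p + 1)])
    B = np.linalg.solve(G.T, g.T).T
    A = [B[:, j * K:(j + 1) * K] for j in range(p)]
    Sig = cov.lag(0).copy()
    for i, a in enumerate(A, 1):
        Sig -= a @ cov.lag(i).T
    return isdm_from_var(VARModel(A, (Sig + Sig.T) / 2)).coeffs


class TestSparsityPromoter:
    def test_zero_for_diagonal(self):
        Z = np.diag([1.0, 2.0, 3.0, 4.0])
        assert sparsity_promoter(Z, 2, order=1, block=2) == 0.0

    def test_single_pair_order_zero(self):
        Z = np.array([[1.0, 0.3], [0.3, 2.0]])
        assert sparsity_promoter(Z, 2, order=0, block=2) == \
            pytest.approx(0.3)

    def test_max_over_lags(self):
        # D_0(2,1) = 0.2, D_1(2,1) = -0.5 -> contribution 0.5
        Z = np.zeros((4, 4))
        Z[1, 0] = Z[0, 1] = 0.2
        Z[1, 2] = Z[2, 1] = -0.5  # D_1(2,1) entry X[1, 2+0]
        assert sparsity_promoter(Z, 2, order=1, block=2) == \
            pytest.approx(0.5)

    def test_upper_cell_of_higher_lag_counts(self):
        # D_1(1,2) lives at X[0, 3]; the (2,1) group must see it
        Z = np.zeros((4, 4))
        Z[0, 3] = Z[3, 0] = -0.7
        assert sparsity_promoter(Z, 2, order=1, block=2) == \
            pytest.approx(0.7)


class TestME1:
    def test_scalar_closed_form(self):
        cov = CovarianceSequence([np.array([[2.0]])])
        sol = solve_me1(cov, **TIGHT)
        assert sol.value[0, 0] == pytest.approx(0.5, abs=1e-6)
        assert sol.objective == pytest.approx(1 + np.log(2), abs=1e-6)

    def test_white_noise_lags(self):
        cov = CovarianceSequence([np.eye(3), np.zeros((3, 3))])
        sol = solve_me1(cov, **TIGHT)
        assert np.abs(sol.D(0) - np.eye(3)).max() < 1e-5
        assert np.abs(sol.D(1)).max() < 1e-5

    @pytest.mark.parametrize("use_sample", [False, True])
    def test_equals_yule_walker(self, stable_var2, use_sample):
        if use_sample:
            ts = simulate_var(stable_var2, 3000, seed=13)
            cov = sample_covariances(ts, 2)
        else:
            cov = theoretical_covariances(stable_var2, 2)
        sol = solve_me1(cov, **TIGHT)
        Q = yule_walker_isdm(cov)
        err = max(np.abs(sol.D(i) - Q[i]).max() for i in range(3))
        assert err < 1e-4

    def test_duality_gap_reported(self, stable_var2):
        cov = theoretical_covariances(stable_var2, 2)
        sol = solve_me1(cov, **TIGHT)
        assert sol.gap < 1e-5
        assert sol.status == "optimal"

    def test_permutation_invariance(self, stable_var2):
        cov = theoretical_covariances(stable_var2, 1)
        perm = np.array([2, 0, 1])
        cov_p = CovarianceSequence([c[np.ix_(perm, perm)]
                                    for c in cov.lags])
        o1 = solve_me1(cov, **TIGHT).objective
        o2 = solve_me1(cov_p, **TIGHT).objective
        assert o1 == pytest.approx(o2, abs=1e-6)

    def test_indefinite_embedding_rejected(self):
        cov = CovarianceSequence([np.eye(2), 2 * np.eye(2)])
        with pytest.raises(SolverError) as err:
            solve_me1(cov)
        assert err.value.status == "indefinite_input"


class TestME2:
    def test_equality_constraints_hold(self, small_synth):
        model, _, _ = small_synth
        cov = theoretical_covariances(model, 1)
        sol = solve_me2(cov, 0.02, K=5, r=1)
        assert abs(sol.D(0)[5, 5] - 1.0) < 1e-6
        assert abs(sol.D(1)[5, 5]) < 1e-6

    def test_identity_covariance_optimum(self):
        m = 5
        cov = CovarianceSequence([np.eye(m), np.zeros((m, m))])
        sol = solve_me2(cov, 0.05, K=4, r=1, **TIGHT)
        assert sol.objective == pytest.approx(m, abs=1e-4)
        assert np.abs(sol.value[:m, :m] - np.eye(m)).max() < 1e-3

    def test_promoter_monotone_in_lambda(self, small_synth):
        model, _, _ = small_synth
        cov = theoretical_covariances(model, 1)
        vals = [sparsity_promoter(solve_me2(cov, lam, K=5, r=1), 5)
                for lam in (0.005, 0.02, 0.05, 0.1)]
        assert all(a >= b - 1e-6 for a, b in zip(vals, vals[1:]))

    def test_negative_lambda_rejected(self, small_synth):
        model, _, _ = small_synth
        cov = theoretical_covariances(model, 1)
        with pytest.raises(ValueError):
            solve_me2(cov, -0.1, K=5, r=1)

    def test_dimension_mismatch(self, stable_var2):
        cov = theoretical_covariances(stable_var2, 1)
        with pytest.raises(ValueError):
            solve_me2(cov, 0.1, K=5, r=1)


class TestME3:
    def test_full_pattern_equals_me2_lambda_zero(self, small_synth):
        model, _, _ = small_synth
        cov = theoretical_covariances(model, 1)
        full = SparsityPattern.full(5)
        o2 = solve_me2(cov, 0.0, K=5, r=1, **TIGHT).objective
        o3 = solve_me3(cov, full, K=5, r=1, **TIGHT).objective
        assert abs(o2 - o3) < 1e-6

    def test_constrained_cells_vanish(self, normalized_latent_model):
        isdm, pattern = normalized_latent_model
        model = spectral_factorize(isdm).to_model()
        cov = theoretical_covariances(model, 1)
        sol = solve_me3(cov, pattern, K=5, r=1)
        adj = pattern.adjacency
        for i in range(2):
            Di = sol.D(i)
            for a in range(5):
                for b in range(5):
                    if a != b and not adj[a, b]:
                        assert abs(Di[a, b]) <= 1e-8

    def test_maximum_entropy_recovery(self, normalized_latent_model):
        """Exact covariances of an in-class sparse model are completed to
        the true ISDM by the constrained maximum-entropy problem."""
        isdm, pattern = normalized_latent_model
        model = spectral_factorize(isdm).to_model()
        cov = theoretical_covariances(model, 1)
        sol = solve_me3(cov, pattern, K=5, r=1, **TIGHT)
        err = max(np.abs(sol.D(i) - isdm.coeffs[i]).max()
                  for i in range(2))
        assert err < 1e-3


class TestSparseLowRank:
    def test_solutions_are_psd(self, small_synth):
        model, _, _ = small_synth
        cov = theoretical_covariances(model, 1).truncate(1)
        cov = CovarianceSequence([c[:5, :5] for c in cov.lags])
        X, L = solve_sparse_lowrank(cov, 0.1, 0.1)
        assert X.min_eigenvalue() > -1e-6
        assert L.min_eigenvalue() > -1e-6

    def test_lambda_to_zero_recovers_me1(self, stable_var2):
        cov = theoretical_covariances(stable_var2, 1)
        base = solve_me1(cov, **TIGHT)
        X, L = solve_sparse_lowrank(cov, 1e-7, 1.0, **TIGHT)
        # same objective once the vanishing penalty terms are dropped
        from vargraph.varsim import block_toeplitz
        Tm = block_toeplitz(cov)
        def raw_obj(M):
            return (np.sum(Tm * M.value)
                    - np.linalg.slogdet(M.value[:3, :3])[1])
        assert abs(raw_obj(X) - raw_obj(base)) < 1e-4

    def test_low_rank_recovery_on_synthetic(self, small_synth):
        model, _, _ = small_synth
        cov = theoretical_covariances(model, 1)
        cov_manifest = CovarianceSequence([c[:5, :5] for c in cov.lags])
        X, L = solve_sparse_lowrank(cov_manifest, 0.05, 2.0,
                                    gap_tol=1e-7)
        w = np.linalg.eigvalsh(L.value)
        assert w.max() > 0.1  # the latent component is actually picked up
        assert (w > 1e-3 * w.max()).sum() <= 1

    def test_invalid_parameters(self, small_synth):
        model, _, _ = small_synth
        cov = theoretical_covariances(model, 1)
        cov = CovarianceSequence([c[:5, :5] for c in cov.lags])
        with pytest.raises(ValueError):
            solve_sparse_lowrank(cov, 0.0, 0.5)
        with pytest.raises(ValueError):
            solve_sparse_lowrank(cov, 0.5, -1.0)
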