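"""VAR simulation, covariances, ISDM construction and the generator."""

import json

import numpy as np
import pytest

from vargraph.varsim import (CovarianceSequence, SparsityPattern,
                             TimeSeries, TrigMatrixPolynomial, VARModel,
                             block_toeplitz, block_trace,
                             generate_synthetic_model, isdm_from_var,
                             omega_grid, pattern_distance,
                             read_timeseries, sample_covariances,
                             simulate_var, theoretical_covariances,
                             write_timeseries)



class TestSimulate:
    def test_white_noise_lag_one_vanishes(self):
        model = VARModel([np.zeros((3, 3))], np.eye(3))
        T = 20_000
        ts = simulate_var(model, T, seed=0)
        c1 = sample_covariances(ts, 1).lags[1]
        assert np.abs(c1).max() < 5 / np.sqrt(T)

    def test_deterministic_given_seed(self, stable_var2):
        a = simulate_var(stable_var2, 500, seed=42)
        b = simulate_var(stable_var2, 500, seed=42)
        np.testing.assert_array_equal(a.data, b.data)
        c = simulate_var(stable_var2, 500, seed=43)
        assert not np.allclose(a.data, c.data)

    def test_unstable_model_rejected(self):
        model = VARModel.__new__(VARModel)
        model.coeffs = [np.array([[1.05]])]
        model.noise_cov = np.array([[1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            simulate_var(model, 10, seed=0)

    def test_study_length_series(self, small_synth):
        model, _, _ = small_synth
        ts = simulate_var(model, 50_000, seed=5)
        assert ts.data.shape == (50_000, model.dim)


class TestSampleCovariances:
    def test_zero_series(self):
        ts = TimeSeries(np.zeros((10, 2)))
        cov = sample_covariances(ts, 2)
        for lag in cov.lags:
            np.testing.assert_array_equal(lag, np.zeros((2, 2)))

    def test_hand_example_divisor_T(self):
        # x_1 = (1, 0), x_2 = (0, 1); divisor is T, not T - i
        ts = TimeSeries(np.array([[1.0, 0.0], [0.0, 1.0]]))
        cov = sample_covariances(ts, 1)
        np.testing.assert_allclose(cov.lags[0], 0.5 * np.eye(2))
        np.testing.assert_allclose(cov.lags[1],
                                   np.array([[0.0, 0.0], [0.5, 0.0]]))

    def test_iid_converges_to_identity(self):
        rng = np.random.default_rng(1)
        T = 40_000
        ts = TimeSeries(rng.standard_normal((T, 3)))
        cov = sample_covariances(ts, 0)
        assert np.abs(cov.lags[0] - np.eye(3)).max() < 5 / np.sqrt(T)

    def test_too_few_rows_rejected(self):
        ts = TimeSeries(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            sample_covariances(ts, 3)


class TestBlockToeplitz:
    def test_order_zero_returns_lag0(self):
        cov = CovarianceSequence([np.array([[2.0, 0.3], [0.3, 1.0]])])
        np.testing.assert_array_equal(block_toeplitz(cov), cov.lags[0])

    def test_scalar_example(self):
        cov = CovarianceSequence([np.array([[2.0]]), np.array([[1.0]])])
        np.testing.assert_array_equal(block_toeplitz(cov),
                                      np.array([[2.0, 1.0], [1.0, 2.0]]))

    def test_exact_var_covariances_give_psd(self, stable_var2):
        cov = theoretical_covariances(stable_var2, 3)
        w = np.linalg.eigvalsh(block_toeplitz(cov))
        assert w.min() >= -1e-8


class TestBlockTrace:
    def test_two_by_two_blocks(self):
        L00, L01, L11 = (np.arange(4).reshape(2, 2) + i for i in range(3))
        M = np.block([[L00, L01], [L01.T, L11]])
        np.testing.assert_array_equal(block_trace(M, 0, 2), L00 + L11)
        np.testing.assert_array_equal(block_trace(M, 1, 2), L01)

    def test_identity_off_diagonal_zero(self):
        assert np.abs(block_trace(np.eye(6), 1, 2)).max() == 0

    def test_brute_force_and_transpose_relation(self):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((9, 9))
        for i in range(3):
            super_sum = sum(
                M[3 * h: 3 * h + 3, 3 * (h + i): 3 * (h + i) + 3]
                for h in range(3 - i))
            sub_sum = sum(
                M[3 * (h + i): 3 * (h + i) + 3, 3 * h: 3 * h + 3]
                for h in range(3 - i))
            np.testing.assert_allclose(block_trace(M, i, 3), super_sum)
            # D_{-i}(M) (sub-diagonal sum) is D_i of the transpose, transposed
            np.testing.assert_allclose(block_trace(M.T, i, 3), sub_sum.T)
        # for symmetric M the D_{-i} = D_i^T convention follows
        S = M + M.T
        np.testing.assert_allclose(
            block_trace(S.T, 1, 3),
            sum(S[3 * (h + 1): 3 * h + 6, 3 * h: 3 * h + 3]
                for h in range(2)).T)

    def test_offset_out_of_range(self):
        with pytest.raises(ValueError):
            block_trace(np.eye(4), 2, 2)


class TestIsdmFromVar:
    def test_white_noise(self):
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        isdm = isdm_from_var(VARModel([], S))
        np.testing.assert_allclose(isdm.coeffs[0], np.linalg.inv(S))

    def test_scalar_ar1_closed_form(self, ar1_scalar):
        isdm = isdm_from_var(ar1_scalar)
        assert isdm.coeffs[0][0, 0] == pytest.approx(1.25)
        assert isdm.coeffs[1][0, 0] == pytest.approx(-0.5)

    def test_matches_direct_evaluation(self, stable_var2):
        isdm = isdm_from_var(stable_var2)
        omegas = omega_grid(64)
        Sinv = np.linalg.inv(stable_var2.noise_cov)
        k = stable_var2.dim
        for w, val in zip(omegas, isdm.evaluate(omegas)):
            A = -np.eye(k, dtype=complex)
            for i, a in enumerate(stable_var2.coeffs, 1):
                A = A + a * np.exp(-1j * w * i)
            A = -A
            direct = A.conj().T @ Sinv @ A
            assert np.abs(val - direct).max() < 1e-10

    def test_positive_definite_on_grid(self, stable_var2):
        assert isdm_from_var(stable_var2).min_eigenvalue(512) > 0


class TestTheoreticalCovariances:
    def test_white_noise(self):
        cov = theoretical_covariances(VARModel([np.zeros((2, 2))],
                                               np.eye(2)), 2)
        np.testing.assert_allclose(cov.lags[0], np.eye(2), atol=1e-12)
        np.testing.assert_allclose(cov.lags[1], 0 * np.eye(2), atol=1e-12)

    def test_scalar_ar1_closed_form(self, ar1_scalar):
        cov = theoretical_covariances(ar1_scalar, 2)
        assert cov.lags[0][0, 0] == pytest.approx(4 / 3)
        assert cov.lags[1][0, 0] == pytest.approx(2 / 3)
        assert cov.lags[2][0, 0] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("T", [1000, 10_000, 100_000])
    def test_sample_convergence(self, stable_var2, T):
        ts = simulate_var(stable_var2, T, seed=T)
        sc = sample_covariances(ts, 2)
        tc = theoretical_covariances(stable_var2, 2)
        err = max(np.abs(sc.lags[i] - tc.lags[i]).max() for i in range(3))
        assert err < 25 / np.sqrt(T)


class TestGenerator:
    def test_prescribed_entries(self):
        _, pattern, isdm = generate_synthetic_model(
            KS=2, K=6, r=1, p=1, seed=4, positions=[(2, 0), (4, 1)])
        Q0, Q1 = isdm.coeffs
        assert Q0[2, 0] == pytest.approx(0.5)
        assert Q1[2, 0] == pytest.approx(0.25)
        assert Q0[6, 1] == pytest.approx(0.3)  # latent coupling
        assert Q1[6, 1] == pytest.approx(0.15)
        assert pattern.edges() == [(2, 0), (4, 1)]

    def test_scale_fifty(self):
        _, _, isdm = generate_synthetic_model(
            KS=1, K=4, r=1, p=1, scale=50.0, seed=0, positions=[(3, 1)])
        assert isdm.coeffs[0][3, 1] == pytest.approx(25.0)
        assert isdm.coeffs[1][3, 1] == pytest.approx(12.5)
        assert isdm.coeffs[0][4, 0] == pytest.approx(15.0)
        assert isdm.coeffs[1][4, 0] == pytest.approx(7.5)

    def test_roundtrip_through_factorization(self, small_synth):
        model, _, isdm = small_synth
        back = isdm_from_var(model)
        err = max(np.abs(a - b).max()
                  for a, b in zip(back.coeffs, isdm.coeffs))
        assert err < 1e-6

    def test_pattern_zero_cells_are_exact_zeros(self, small_synth):
        _, pattern, isdm = small_synth
        K = pattern.K
        for Q in isdm.coeffs:
            manifest = Q[:K, :K]
            assert np.abs(manifest[~pattern.adjacency]).max() == 0.0

    def test_isdm_positive_definite(self, small_synth):
        _, _, isdm = small_synth
        assert isdm.min_eigenvalue(512) > 1e-8

    def test_ks_out_of_range(self):
        with pytest.raises(ValueError):
            generate_synthetic_model(KS=11, K=5)

    def test_returned_model_is_stable(self, small_synth):
        model, _, _ = small_synth
        assert model.is_stable()


class TestPatternDistance:
    def test_identical(self):
        p = SparsityPattern.from_edges(5, [(2, 0)])
        assert pattern_distance(p, p) == 0

    def test_single_cell(self):
        a = SparsityPattern.from_edges(5, [(2, 0)])
        b = SparsityPattern.diagonal(5)
        assert pattern_distance(a, b) == 1

    def test_full_vs_sparse_at_k15(self):
        full = SparsityPattern.full(15)
        sparse = SparsityPattern.from_edges(15, [(3, 1), (10, 2)])
        assert pattern_distance(full, sparse) == 103

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            pattern_distance(SparsityPattern.full(3),
                             SparsityPattern.full(4))

    def test_metric_properties_random_triples(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            pats = []
            for _ in range(3):
                adj = rng.random((6, 6)) < 0.4
                pats.append(SparsityPattern(adj | adj.T))
            a, b, c = pats
            assert pattern_distance(a, b) == pattern_distance(b, a)
            assert pattern_distance(a, a) == 0
            assert (pattern_distance(a, c) <=
                    pattern_distance(a, b) + pattern_distance(b, c))

    def test_counts_consistent(self):
        p = SparsityPattern.from_edges(15, [(3, 1), (10, 2)])
        assert p.K_bar == 105
        assert p.KS == 2
        assert p.N0 == 103
        assert p.N0 + p.KS == p.K_bar


class TestIO:
    def test_timeseries_roundtrip(self, tmp_path, stable_var2):
        ts = simulate_var(stable_var2, 50, seed=3,
                          names=["a", "b", "c"])
        path = tmp_path / "series.csv"
        write_timeseries(ts, path)
        back = read_timeseries(path)
        np.testing.assert_array_equal(back.data, ts.data)
        assert back.names == ts.names

    def test_model_json_roundtrip(self, tmp_path, stable_var2):
        path = tmp_path / "model.json"
        stable_var2.to_json(path, seed=7)
        back = VARModel.from_json(path)
        assert back.p == stable_var2.p
        for a, b in zip(back.coeffs, stable_var2.coeffs):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(back.noise_cov,
                                      stable_var2.noise_cov)
        assert json.loads(stable_var2.to_json(seed=7))["seed"] == 7


class TestTrigPolynomial:
    def test_hermitian_evaluation(self, small_synth):
        _, _, isdm = small_synth
        vals_pos = isdm.evaluate(np.array([0.7]))[0]
        vals_neg = isdm.evaluate(np.array([-0.7]))[0]
        np.testing.assert_allclose(vals_neg, vals_pos.conj().T, atol=1e-12)
        np.testing.assert_allclose(vals_pos, vals_pos.conj().T, atol=1e-12)

    def test_latent_manifest_coefficient_symmetry(self, small_synth):
        _, _, isdm = small_synth
        lm = isdm.latent_manifest_coeffs()
        K = isdm.block_sizes[0]
        np.testing.assert_allclose(lm[-1], isdm.coeffs[1][:K, K:].T)
        np.testing.assert_allclose(lm[0], isdm.coeffs[0][K:, :K])
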