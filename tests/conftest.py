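"""Shared fixtures: small deterministic models and series."""

import numpy as np
import pytest

from vargraph.varsim import (SparsityPattern, TrigMatrixPolynomial,
                             VARModel, generate_synthetic_model,
                             simulate_var)


@pytest.fixture(scope="session")
def ar1_scalar():
    """Scalar AR(1): a = 0.5, sigma^2 = 1."""
    return VARModel([np.array([[0.5]])], np.array([[1.0]]))


def random_stable_var(dim, p, seed, coeff_scale=0.35, margin=0.05):
    """Random stable VAR used across test modules."""
    rng = np.random.default_rng(seed)
    while True:
        coeffs = [coeff_scale / (i + 1) * rng.standard_normal((dim, dim))
                  for i in range(p)]
        S = rng.standard_normal((dim, dim))
        S = S @ S.T + 0.5 * np.eye(dim)
        model = VARModel(coeffs, S)
        if model.is_stable(margin):
            return model


@pytest.fixture(scope="session")
def stable_var2():
    return random_stable_var(3, 2, seed=7)


@pytest.fixture(scope="session")
def small_synth():
    """Small latent-variable study model (K=5, KS=2)."""
    model, pattern, isdm = generate_synthetic_model(KS=2, K=5, r=1, p=1,
                                                    seed=3)
    return model, pattern, isdm


def latent_normalized_isdm(K=5, KS=2, seed=11):
    """A pattern-sparse ISDM whose latent block is exactly (I, 0).

    Such a model lies inside the estimator's model class (latent variance
    one, conditionally independent latents), so maximum-entropy recovery
    from its exact covariances is exact.
    """
    rng = np.random.default_rng(seed)
    kappa = K + 1
    low = list(zip(*np.tril_indices(K, -1)))
    idx = rng.choice(len(low), KS, replace=False)
    pos = [(int(low[i][0]), int(low[i][1])) for i in idx]
    Q0 = 4.0 * np.eye(kappa)
    Q1 = np.zeros((kappa, kappa))
    np.fill_diagonal(Q1, 0.3)
    Q0[K, K], Q1[K, K] = 1.0, 0.0
    for a, b in pos:
        Q0[a, b] = Q0[b, a] = 0.5
        Q1[a, b] = Q1[b, a] = 0.25
    for b in range(K):
        Q0[K, b] = Q0[b, K] = 0.3
        Q1[K, b] = Q1[b, K] = 0.15
    isdm = TrigMatrixPolynomial([Q0, Q1], block_sizes=(K, 1))
    assert isdm.min_eigenvalue() > 1e-3
    pattern = SparsityPattern.from_edges(K, pos)
    return isdm, pattern


@pytest.fixture(scope="session")
def normalized_latent_model():
    return latent_normalized_isdm()


@pytest.fixture(scope="session")
def small_series(small_synth):
    model, pattern, _ = small_synth
    return simulate_var(model, 6000, seed=21).manifest(5), pattern
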