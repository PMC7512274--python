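"""Spectral factorization of positive matrix trigonometric polynomials.

An ISDM estimate ``Phi^{-1}(omega) = sum_{i=-p}^p Q_i e^{-j omega i}`` that
is positive definite on the unit circle admits a unique factorization
``Phi^{-1}(omega) = A(omega)^H Sigma^{-1} A(omega)`` with
``A(omega) = -sum_{i=0}^p A_i e^{-j omega i}``, ``A_0 = -I``, ``Sigma``
positive definite and the factor minimum phase (the recovered VAR model is
stable).  The factorization is computed through the innovations form of a
moving-average covariance model: writing ``Q_i^T`` as the covariance lags
of an MA(p) process, the stabilizing solution of the associated discrete
Riccati equation yields the minimum-phase MA polynomial, from which the
normalized VAR coefficients follow.

The Riccati equation is solved by the monotone fixed-point iteration
``P <- A P A^T + (G - A P C^T)(Q0^T - C P C^T)^{-1} (G - A P C^T)^T``
started at ``P = 0``, which converges to the stabilizing solution for any
spectrum that is positive definite on the circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .varsim import TimeSeries, TrigMatrixPolynomial, VARModel

__all__ = ["SpectralFactor", "spectral_factorize", "manifest_truncate",
           "residual_covariance"]


@dataclass
class SpectralFactor:
    """Minimum-phase VAR factor: coefficients ``A_1..A_p`` and ``Sigma``."""

    ar_coeffs: list[np.ndarray]
    sigma: np.ndarray

    @property
    def p(self) -> int:
        return len(self.ar_coeffs)

    @property
    def dim(self) -> int:
        return self.sigma.shape[0]

    def to_model(self) -> VARModel:
        return VARModel(self.ar_coeffs, self.sigma)


def _ma_factor_riccati(R: list[np.ndarray], tol: float = 1e-14,
                       max_iter: int = 200_000):
    """Minimum-phase factor ``D_0..D_p`` with
    ``sum_k D_{k+i} D_k^T = R_i`` for ``i = 0..p`` (zero beyond ``p``)."""
    p = len(R) - 1
    m = R[0].shape[0]
    if p == 0:
        return [np.linalg.cholesky((R[0] + R[0].T) / 2)]
    n = p * m
    # shift-up realization: C A^{i-1} G = R_i for i = 1..p
    A = np.zeros((n, n))
    for j in range(p - 1):
        A[j * m:(j + 1) * m, (j + 1) * m:(j + 2) * m] = np.eye(m)
    G = np.vstack(R[1:])
    C = np.zeros((m, n))
    C[:, :m] = np.eye(m)
    L0 = (R[0] + R[0].T) / 2

    P = np.zeros((n, n))
    last = np.inf
    for _ in range(max_iter):
        S = L0 - C @ P @ C.T
        try:
            Sc = np.linalg.cholesky((S + S.T) / 2)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "spectral factorization failed: innovation covariance "
                "lost positive definiteness") from exc
        Kt = G - A @ P @ C.T
        W = np.linalg.solve(Sc, Kt.T).T  # Kt Sc^{-T}
        P_new = A @ P @ A.T + W @ W.T
        delta = np.abs(P_new - P).max()
        P = (P_new + P_new.T) / 2
        if delta < tol * max(1.0, np.abs(P).max()):
            break
        if delta > 1e12 or not np.isfinite(delta):
            raise ValueError("spectral factorization diverged")
        last = delta
    S = L0 - C @ P @ C.T
    Sc = np.linalg.cholesky((S + S.T) / 2)  # S = Sc Sc^T
    Kgain = np.linalg.solve(S, (G - A @ P @ C.T).T).T  # (G-APC')S^{-1}
    D = [Sc] + [C @ np.linalg.matrix_power(A, k - 1) @ Kgain @ Sc
                for k in range(1, p + 1)]
    return D


def spectral_factorize(isdm: TrigMatrixPolynomial,
                       freq_grid: int = 512,
                       pd_tol: float = 0.0) -> SpectralFactor:
    """Factor a positive ISDM polynomial into a stable VAR model.

    Returns the unique minimum-phase factor normalized to ``A_0 = -I``.
    """
    if isdm.min_eigenvalue(freq_grid) <= pd_tol:
        raise ValueError(
            "ISDM polynomial is not positive definite on the frequency grid")
    p = isdm.degree
    # MA covariance lags for the transposed-order problem
    R = [isdm.coeffs[i].T for i in range(p + 1)]
    D = _ma_factor_riccati(R)
    # C_k = D_k^T give Q(w) = C(w)^H C(w); normalize A(w) = -C_0^{-1} C(w)
    C0 = D[0].T
    Cs = [d.T for d in D]
    A = [np.linalg.solve(C0, Cs[i]) for i in range(1, p + 1)]
    sigma = np.linalg.inv(C0.T @ C0)
    sigma = (sigma + sigma.T) / 2
    factor = SpectralFactor([-a for a in A], sigma)
    factor.to_model().assert_stable()
    return factor


def manifest_truncate(factor: SpectralFactor, K: int) -> SpectralFactor:
    """Keep only the manifest (upper-left ``K x K``) blocks of the factor."""
    if K > factor.dim:
        raise ValueError("K exceeds the factor dimension")
    return SpectralFactor([a[:K, :K].copy() for a in factor.ar_coeffs],
                          factor.sigma[:K, :K].copy())


def residual_covariance(series: TimeSeries, coeffs) -> np.ndarray:
    """One-step-ahead residual covariance ``(1/(T-p)) sum e_t e_t^T``."""
    X = series.data
    T = X.shape[0]
    p = len(coeffs)
    if T <= p:
        raise ValueError("series too short for the given order")
    E = X[p:].copy()
    for i, a in enumerate(coeffs, start=1):
        E -= X[p - i: T - i] @ np.asarray(a).T
    return (E.T @ E) / (T - p)
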