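"""Model-selection layer: effective parameter counts, information-theoretic
criteria, the Bartlett correlogram, the relative entropy rate and the score
functions used to pick a sparsity pattern from a candidate set.

All criteria share the convention "smaller is better".  The goodness-of-fit
term is built from the residual covariance ``Sigma_hat`` of the fitted
manifest VAR model; the penalties use the effective number of parameters

    Nef = K(K+1)/2 - N0 + p (K^2 - 2 N0),

where ``N0`` counts the zeros strictly below the diagonal of the sparsity
pattern.  The extended criteria additionally account for the size of the
model family (the number of patterns with the same sparsity), and the
renormalized-maximum-likelihood pair RNML / RNMLFD uses the closed form
for Gaussian VAR models with a data-dependent penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, multigammaln

from .varsim import (DEFAULT_FREQ_GRID, SparsityPattern, TimeSeries,
                     TrigMatrixPolynomial, autocovariances, omega_grid)

__all__ = [
    "CRITERIA", "SCORE_FUNCTIONS", "SELECTORS", "SelectionScores",
    "effective_params", "n_edges", "compute_itc", "correlogram_bartlett",
    "relative_entropy_rate", "score_functions",
]

CRITERIA = ("SBC", "AICc", "logFPE", "RNML", "EBIC", "EBICFD", "RNMLFD")
SCORE_FUNCTIONS = ("SF1", "SF2", "SF3")
SELECTORS = CRITERIA + SCORE_FUNCTIONS


def effective_params(sp: SparsityPattern, p: int) -> int:
    """Effective number of parameters of a sparse VAR model."""
    K, N0 = sp.K, sp.N0
    return K * (K + 1) // 2 - N0 + p * (K * K - 2 * N0)


def n_edges(sp: SparsityPattern, r: int = 1) -> int:
    """Total edge count ``Ne`` including latent-manifest edges.

    For a single latent variable this is ``K(K+1)/2 - N0``; the general
    form ``K(K-1)/2 - N0 + rK`` assumes every latent variable is coupled
    to every manifest one.
    """
    K, N0 = sp.K, sp.N0
    return K * (K - 1) // 2 - N0 + r * K


def _logdet_pd(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0:
        raise ValueError("matrix must be positive definite")
    return float(ld)


def compute_itc(name: str, sigma_hat: np.ndarray, r0_hat: np.ndarray,
                n_ef: int, T: int, K: int, gamma: float = 1.0,
                N0: int | None = None) -> float:
    """Evaluate one information-theoretic criterion.

    ``r0_hat`` is the lag-zero sample covariance of the manifest series
    (used only by the RNML family).  ``N0`` (below-diagonal zero count) is
    required by EBIC, whose family-size term counts patterns with the same
    sparsity.
    """
    ld = _logdet_pd(sigma_hat)
    K_bar = K * (K - 1) // 2
    eta = n_ef / K
    if name == "SBC":
        return T * ld + n_ef * math.log(T)
    if name == "AICc":
        if T <= n_ef + 1:
            raise ValueError("AICc requires T > Nef + 1")
        return T * ld + 2.0 * n_ef * T / (T - n_ef - 1)
    if name == "logFPE":
        return ld + K * math.log((T + eta) / (T - eta))
    if name in ("RNML", "RNMLFD"):
        tr = float(np.trace(r0_hat - sigma_hat))
        if tr <= 0:
            raise ValueError("RNML requires tr(R0_hat - Sigma_hat) > 0")
        val = ((T - eta - K + 1) / 2.0 * ld
               + n_ef / 2.0 * math.log(tr)
               - multigammaln((T - eta) / 2.0, K)
               - gammaln(n_ef / 2.0))
        if name == "RNMLFD":
            val += 2.0 * n_ef * math.log(K)
        return float(val)
    if name in ("EBIC", "EBICFD"):
        sbc = T * ld + n_ef * math.log(T)
        if name == "EBICFD":
            return float(sbc + 4.0 * gamma * n_ef * math.log(K))
        if N0 is None:
            raise ValueError("EBIC requires the below-diagonal zero count N0")
        log_binom = gammaln(K_bar + 1) - gammaln(N0 + 1) - gammaln(
            K_bar - N0 + 1)
        return float(sbc + 2.0 * gamma * log_binom)
    raise ValueError(f"unknown criterion {name!r}")


@dataclass
class SelectionScores:
    """Criterion and score-function values for one candidate pattern."""

    n_ef: int
    n_e: int
    K: int
    values: dict = field(default_factory=dict)
    gamma: float = 1.0

    @property
    def eta(self) -> float:
        return self.n_ef / self.K


def score_all_criteria(sigma_hat, r0_hat, sp: SparsityPattern, p: int,
                       T: int, gamma: float = 1.0,
                       entropy_rate: float | None = None,
                       r: int = 1) -> dict:
    """All criteria (and, if ``entropy_rate`` given, score functions)."""
    K = sp.K
    n_ef = effective_params(sp, p)
    n_e = n_edges(sp, r)
    out = {}
    for name in CRITERIA:
        try:
            out[name] = compute_itc(name, sigma_hat, r0_hat, n_ef, T, K,
                                    gamma, N0=sp.N0)
        except ValueError:
            out[name] = np.nan
    if entropy_rate is not None:
        try:
            sf1, sf2, sf3 = score_functions(entropy_rate, n_e, T)
            out["SF1"], out["SF2"], out["SF3"] = sf1, sf2, sf3
        except ValueError:
            out["SF1"] = out["SF2"] = out["SF3"] = np.nan
    return out


def correlogram_bartlett(series: TimeSeries, window_len: int | None = None,
                         freq_grid: int = DEFAULT_FREQ_GRID):
    """Bartlett-windowed correlogram evaluated on the frequency grid.

    Returns ``(poly, evals)``: the lag-weighted trigonometric polynomial
    ``sum_{|i|<=M} (1 - |i|/(M+1)) R_i e^{-j w i}`` and its evaluations on
    the default grid, eigenvalue-clipped to be positive definite when the
    raw correlogram is indefinite.
    """
    T = series.T
    if window_len is None:
        window_len = int(math.floor(math.sqrt(T)))
    M = int(window_len)
    if M >= T:
        raise ValueError("window length must be smaller than T")
    lags = autocovariances(series.data, M)
    weights = 1.0 - np.arange(M + 1) / (M + 1.0)
    poly = TrigMatrixPolynomial([w * c for w, c in zip(weights, lags)])
    evals = poly.evaluate(omega_grid(freq_grid))
    # clip tiny/negative eigenvalues so downstream log-dets are defined
    w_min = np.linalg.eigvalsh(evals)[:, 0].min()
    if w_min <= 0:
        lam, V = np.linalg.eigh(evals)
        floor = 1e-10 * np.abs(lam).max()
        lam = np.clip(lam, floor, None)
        evals = V @ (lam[..., None] * np.swapaxes(V.conj(), -1, -2))
    return poly, evals


def relative_entropy_rate(phi_num, phi_den=None, den_inverse=None,
                          freq_grid: int = DEFAULT_FREQ_GRID) -> float:
    """Relative entropy rate between two spectral densities.

    ``D = -(1/4 pi) \\int [logdet Omega + tr(I - Omega)] d omega`` with
    ``Omega = Phi_num Phi_den^{-1}``; nonnegative and zero iff the spectra
    coincide.  Arguments may be polynomials or precomputed grid
    evaluations; ``den_inverse`` may be supplied directly instead of
    ``phi_den``.
    """
    grid = omega_grid(freq_grid)
    num = phi_num.evaluate(grid) if isinstance(
        phi_num, TrigMatrixPolynomial) else np.asarray(phi_num)
    if den_inverse is not None:
        den_inv = np.asarray(den_inverse)
        omega = num @ den_inv
    else:
        den = phi_den.evaluate(grid) if isinstance(
            phi_den, TrigMatrixPolynomial) else np.asarray(phi_den)
        omega = np.linalg.solve(np.swapaxes(den, -1, -2), np.swapaxes(
            num, -1, -2))
        omega = np.swapaxes(omega, -1, -2)
    m = omega.shape[-1]
    sign, ld = np.linalg.slogdet(omega)
    if np.any(sign.real <= 0):
        raise ValueError("spectra must be positive definite on the grid")
    tr = np.trace(omega, axis1=-2, axis2=-1).real
    integrand = ld.real + (m - tr)
    d = -0.5 * float(integrand.mean())
    return d


def score_functions(d: float, n_e: int, T: int):
    """Score functions ``(log SF1, SF2, SF3)`` from the entropy rate ``d``.

    ``log SF1 = log d + log Ne``; ``SF2 = d + Ne/T``;
    ``SF3 = d + Ne log T / T``.
    """
    if n_e < 1:
        raise ValueError("Ne must be at least 1")
    if d <= 0:
        raise ValueError("SF1 requires a positive entropy rate")
    log_sf1 = math.log(d) + math.log(n_e)
    sf2 = d + n_e / T
    sf3 = d + n_e * math.log(T) / T
    return log_sf1, sf2, sf3
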