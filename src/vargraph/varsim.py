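"""Vector-autoregressive processes and their spectral representations.

This module holds the generative side of the package: stable VAR(p)
processes, their simulation, exact (Lyapunov) and sample autocovariances,
the inverse spectral density matrix (ISDM) as a Hermitian matrix
trigonometric polynomial, conditional-independence sparsity patterns, and
the synthetic latent-variable model generator used by the simulation
studies.

Conventions
-----------
* A VAR(p) process is ``x_t = A_1 x_{t-1} + ... + A_p x_{t-p} + eps_t``
  with Gaussian innovations of covariance ``Sigma``.  The polynomial
  ``A(omega) = -sum_{i=0}^p A_i e^{-j omega i}`` uses ``A_0 = -I`` so that
  the ISDM is ``Phi^{-1}(omega) = A(omega)^H Sigma^{-1} A(omega)``.
* Covariance lags are ``C_i = E[x_{t+i} x_t^T]`` and their sample analogue
  uses the biased divisor ``T`` (not ``T - i``), which keeps the
  block-Toeplitz embedding positive semidefinite.
* Frequency grids are uniform on ``(-pi, pi]``, 512 points by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

__all__ = [
    "VARModel",
    "TimeSeries",
    "CovarianceSequence",
    "TrigMatrixPolynomial",
    "SparsityPattern",
    "omega_grid",
    "simulate_var",
    "sample_covariances",
    "autocovariances",
    "block_toeplitz",
    "block_trace",
    "isdm_from_var",
    "theoretical_covariances",
    "generate_synthetic_model",
    "pattern_distance",
    "read_timeseries",
    "write_timeseries",
]

DEFAULT_FREQ_GRID = 512


def omega_grid(n: int = DEFAULT_FREQ_GRID) -> np.ndarray:
    """Uniform frequency grid on ``(-pi, pi]`` with ``n`` points."""
    return -np.pi + 2.0 * np.pi * np.arange(1, n + 1) / n


def _as_matrix_list(mats) -> list[np.ndarray]:
    return [np.asarray(m, dtype=float) for m in mats]


@dataclass
class VARModel:
    """A stable Gaussian VAR(p) process.

    Parameters
    ----------
    coeffs : list of (dim, dim) arrays
        Autoregressive matrices ``A_1 .. A_p``; the list may be empty for
        white noise (``p = 0``).
    noise_cov : (dim, dim) array
        Innovation covariance ``Sigma`` (symmetric positive definite).
    """

    coeffs: list[np.ndarray]
    noise_cov: np.ndarray

    def __post_init__(self):
        self.coeffs = _as_matrix_list(self.coeffs)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        k = self.noise_cov.shape[0]
        if self.noise_cov.shape != (k, k):
            raise ValueError("noise_cov must be square")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-10):
            raise ValueError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(self.noise_cov)[0] <= 0:
            raise ValueError("noise_cov must be positive definite")
        for a in self.coeffs:
            if a.shape != (k, k):
                raise ValueError("coefficient matrices must match noise_cov")

    @property
    def p(self) -> int:
        return len(self.coeffs)

    @property
    def dim(self) -> int:
        return self.noise_cov.shape[0]

    def companion(self) -> np.ndarray:
        """Companion matrix of the autoregression (kp x kp)."""
        k, p = self.dim, self.p
        if p == 0:
            return np.zeros((0, 0))
        F = np.zeros((k * p, k * p))
        F[:k, :] = np.hstack(self.coeffs)
        if p > 1:
            F[k:, : k * (p - 1)] = np.eye(k * (p - 1))
        return F

    def is_stable(self, tol: float = 0.0) -> bool:
        if self.p == 0:
            return True
        return self.max_companion_modulus() < 1.0 - tol

    def max_companion_modulus(self) -> float:
        if self.p == 0:
            return 0.0
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    def assert_stable(self) -> None:
        if not self.is_stable():
            raise ValueError(
                "VAR model is unstable: companion eigenvalue modulus "
                f"{self.max_companion_modulus():.6f} >= 1"
            )

    # -- serialization -------------------------------------------------
    def to_json(self, path=None, seed=None) -> str:
        doc = {
            "p": self.p,
            "dim": self.dim,
            "coeffs": [a.tolist() for a in self.coeffs],
            "noise_cov": self.noise_cov.tolist(),
        }
        if seed is not None:
            doc["seed"] = int(seed)
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "VARModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(coeffs=doc["coeffs"], noise_cov=doc["noise_cov"])


@dataclass
class TimeSeries:
    """A multivariate series: ``T`` rows (time) by ``kappa`` columns."""

    data: np.ndarray
    names: list[str] = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x kappa matrix")
        if self.names is None:
            self.names = [f"x{i + 1}" for i in range(self.data.shape[1])]
        if len(self.names) != self.data.shape[1]:
            raise ValueError("names length must equal number of columns")

    @property
    def T(self) -> int:
        return self.data.shape[0]

    @property
    def dim(self) -> int:
        return self.data.shape[1]

    def manifest(self, K: int) -> "TimeSeries":
        """Drop all but the first ``K`` (observed) columns."""
        return TimeSeries(self.data[:, :K], self.names[:K])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.names)


def read_timeseries(path, sep=None) -> TimeSeries:
    """Read a delimited text table (header row, T data rows).

    The delimiter (comma or tab) is sniffed when ``sep`` is None; floats
    are parsed with the round-trip parser so writing and re-reading a
    series is bit-exact.
    """
    if sep is None:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return TimeSeries(df.to_numpy(dtype=float), list(df.columns))


def write_timeseries(series: TimeSeries, path, sep=",") -> None:
    series.to_frame().to_csv(path, sep=sep, index=False)


@dataclass
class CovarianceSequence:
    """Covariance lags ``C_0 .. C_q``; ``C_{-i}`` is implied as ``C_i^T``."""

    lags: list[np.ndarray]

    def __post_init__(self):
        self.lags = _as_matrix_list(self.lags)
        m = self.lags[0].shape[0]
        for c in self.lags:
            if c.shape != (m, m):
                raise ValueError("all lags must be square of equal size")

    @property
    def q(self) -> int:
        return len(self.lags) - 1

    @property
    def dim(self) -> int:
        return self.lags[0].shape[0]

    def lag(self, i: int) -> np.ndarray:
        """Lag ``i`` for ``-q <= i <= q`` (negative via transposition)."""
        if abs(i) > self.q:
            raise IndexError(f"lag {i} not stored (q = {self.q})")
        return self.lags[i] if i >= 0 else self.lags[-i].T

    def truncate(self, q: int) -> "CovarianceSequence":
        return CovarianceSequence(self.lags[: q + 1])


class TrigMatrixPolynomial:
    """Hermitian matrix trigonometric polynomial with real coefficients.

    Represents ``P(omega) = sum_{i=-d}^{d} P_i e^{-j omega i}`` where only
    ``P_0 .. P_d`` are stored and ``P_{-i} = P_i^T`` (Hermitian extension).
    Used for spectral density matrices and their inverses.
    """

    def __init__(self, coeffs, block_sizes=None):
        self.coeffs = _as_matrix_list(coeffs)
        m = self.coeffs[0].shape[0]
        for c in self.coeffs:
            if c.shape != (m, m):
                raise ValueError("coefficients must be square, equal size")
        if block_sizes is not None:
            K, r = block_sizes
            if K + r != m:
                raise ValueError("block sizes must sum to the dimension")
        self.block_sizes = block_sizes

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    @property
    def dim(self) -> int:
        return self.coeffs[0].shape[0]

    def __call__(self, omegas) -> np.ndarray:
        return self.evaluate(omegas)

    def evaluate(self, omegas) -> np.ndarray:
        """Evaluate at frequencies; returns (n, m, m) complex Hermitian."""
        w = np.atleast_1d(np.asarray(omegas, dtype=float))
        C = np.stack(self.coeffs)  # (d+1, m, m)
        phase = np.exp(-1j * np.outer(w, np.arange(self.degree + 1)))
        vals = np.einsum("ni,imk->nmk", phase, C)
        if self.degree > 0:
            Ct = np.stack([c.T for c in self.coeffs[1:]])
            phase_neg = np.exp(1j * np.outer(w, np.arange(1, self.degree + 1)))
            vals += np.einsum("ni,imk->nmk", phase_neg, Ct)
        return vals

    def min_eigenvalue(self, freq_grid: int = DEFAULT_FREQ_GRID) -> float:
        vals = self.evaluate(omega_grid(freq_grid))
        return float(np.linalg.eigvalsh(vals)[:, 0].min())

    def is_positive_definite(self, freq_grid: int = DEFAULT_FREQ_GRID,
                             tol: float = 1e-8) -> bool:
        return self.min_eigenvalue(freq_grid) > tol

    def manifest_part(self) -> "TrigMatrixPolynomial":
        if self.block_sizes is None:
            raise ValueError("block sizes not set")
        K = self.block_sizes[0]
        return TrigMatrixPolynomial([c[:K, :K] for c in self.coeffs])

    def latent_manifest_coeffs(self) -> dict[int, np.ndarray]:
        """Latent-manifest blocks for indices ``-d .. d``.

        Index ``i >= 0`` is the lower-left block of ``P_i``; a negative
        index comes from the Hermitian symmetry ``P_{-i} = P_i^T`` (the
        transposed upper-right block of ``P_i``).
        """
        if self.block_sizes is None:
            raise ValueError("block sizes not set")
        K, r = self.block_sizes
        out = {}
        for i, c in enumerate(self.coeffs):
            out[i] = c[K:, :K].copy()
            out[-i] = c[:K, K:].T.copy()
        return out


@dataclass
class SparsityPattern:
    """Symmetric boolean adjacency of the conditional-independence graph."""

    adjacency: np.ndarray

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=bool).copy()
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(adj, True)
        self.adjacency = adj

    @classmethod
    def from_edges(cls, K: int, edges) -> "SparsityPattern":
        adj = np.eye(K, dtype=bool)
        for a, b in edges:
            adj[a, b] = adj[b, a] = True
        return cls(adj)

    @classmethod
    def full(cls, K: int) -> "SparsityPattern":
        return cls(np.ones((K, K), dtype=bool))

    @classmethod
    def diagonal(cls, K: int) -> "SparsityPattern":
        return cls(np.eye(K, dtype=bool))

    @property
    def K(self) -> int:
        return self.adjacency.shape[0]

    @property
    def K_bar(self) -> int:
        return self.K * (self.K - 1) // 2

    @property
    def N0(self) -> int:
        """Zeros strictly below the main diagonal."""
        low = np.tril_indices(self.K, k=-1)
        return int((~self.adjacency[low]).sum())

    @property
    def KS(self) -> int:
        """Nonzeros strictly below the main diagonal."""
        return self.K_bar - self.N0

    def edges(self) -> list[tuple[int, int]]:
        low = np.tril_indices(self.K, k=-1)
        return [(int(a), int(b)) for a, b in zip(*low) if self.adjacency[a, b]]

    def to_text(self) -> str:
        return "\n".join(
            " ".join(str(int(v)) for v in row) for row in self.adjacency
        )


def pattern_distance(a: SparsityPattern, b: SparsityPattern) -> int:
    """Number of strictly-below-diagonal cells where two patterns differ."""
    if a.K != b.K:
        raise ValueError(f"pattern sizes differ: {a.K} vs {b.K}")
    low = np.tril_indices(a.K, k=-1)
    return int((a.adjacency[low] != b.adjacency[low]).sum())


# ---------------------------------------------------------------------------
# Simulation and covariances
# ---------------------------------------------------------------------------

def simulate_var(model: VARModel, T: int, seed=None,
                 burn_in: int = 1000, names=None) -> TimeSeries:
    """Simulate ``T`` observations of a stable VAR process.

    The recursion starts from a zero state; the first ``burn_in`` samples
    are discarded so the output is effectively stationary.  Deterministic
    given ``seed``.
    """
    model.assert_stable()
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    k, p = model.dim, model.p
    L = np.linalg.cholesky(model.noise_cov)
    eps = rng.standard_normal((burn_in + T, k)) @ L.T
    x = np.zeros((burn_in + T + p, k))
    A = model.coeffs
    for t in range(burn_in + T):
        acc = eps[t]
        for i in range(1, p + 1):
            acc = acc + A[i - 1] @ x[t + p - i]
        x[t + p] = acc
    return TimeSeries(x[p + burn_in:], names)


def sample_covariances(series: TimeSeries, p: int) -> CovarianceSequence:
    """Biased sample covariances ``C_i = (1/T) sum_t x_{t+i} x_t^T``."""
    X = series.data
    T = X.shape[0]
    if p >= T:
        raise ValueError(f"need T > p (T={T}, p={p})")
    lags = [(X[i:].T @ X[: T - i]) / T for i in range(p + 1)]
    return CovarianceSequence(lags)


def autocovariances(X: np.ndarray, max_lag: int) -> list[np.ndarray]:
    """All biased covariance lags ``0 .. max_lag`` via FFT (divisor T)."""
    T, k = X.shape
    n = 1
    while n < T + max_lag + 1:
        n *= 2
    F = np.fft.rfft(X, n=n, axis=0)
    # cross-spectra -> cross-covariances for all columns at once
    S = np.einsum("na,nb->nab", F, F.conj())
    acf = np.fft.irfft(S, n=n, axis=0)[: max_lag + 1] / T
    # acf[i][a, b] = sum_t X[t+i, b] X[t, a]; reorder to C_i = E x_{t+i} x_t^T
    return [acf[i].T.copy() for i in range(max_lag + 1)]


def block_toeplitz(cov: CovarianceSequence) -> np.ndarray:
    """Symmetric block-Toeplitz embedding ``T(C)`` of lags ``0..q``."""
    q, m = cov.q, cov.dim
    out = np.empty(((q + 1) * m, (q + 1) * m))
    for h in range(q + 1):
        for k in range(q + 1):
            blk = cov.lags[k - h] if k >= h else cov.lags[h - k].T
            out[h * m:(h + 1) * m, k * m:(k + 1) * m] = blk
    return out


def block_trace(M: np.ndarray, i: int, block: int) -> np.ndarray:
    """Block-trace ``D_i(M)``: sum of super-diagonal blocks at offset ``i``.

    ``D_{-i}(M) = D_i(M)^T`` is obtained by the caller via transposition.
    """
    n = M.shape[0]
    if M.shape != (n, n) or n % block:
        raise ValueError("M must be square with side divisible by block")
    nb = n // block
    if not 0 <= i < nb:
        raise ValueError(f"offset {i} out of range for {nb} blocks")
    out = np.zeros((block, block))
    for h in range(nb - i):
        out += M[h * block:(h + 1) * block,
                 (h + i) * block:(h + i + 1) * block]
    return out


def isdm_from_var(model: VARModel) -> TrigMatrixPolynomial:
    """ISDM coefficients ``Q_i = sum_k A_k^T Sigma^{-1} A_{k+i}``, A_0=-I."""
    p, k = model.p, model.dim
    Sinv = np.linalg.inv(model.noise_cov)
    A = [-np.eye(k)] + [a for a in model.coeffs]
    Q = []
    for i in range(p + 1):
        acc = np.zeros((k, k))
        for kk in range(p + 1 - i):
            acc += A[kk].T @ Sinv @ A[kk + i]
        Q.append(acc)
    return TrigMatrixPolynomial(Q)


def theoretical_covariances(model: VARModel, q: int) -> CovarianceSequence:
    """Exact stationary covariance lags ``0..q`` via the companion-form
    discrete Lyapunov equation."""
    model.assert_stable()
    k, p = model.dim, model.p
    if p == 0:
        lags = [model.noise_cov] + [np.zeros((k, k))] * q
        return CovarianceSequence(lags)
    F = model.companion()
    Qc = np.zeros((k * p, k * p))
    Qc[:k, :k] = model.noise_cov
    S = sla.solve_discrete_lyapunov(F, Qc)
    S = (S + S.T) / 2
    # state (x_t, ..., x_{t-p+1}): block (0, j) is E[x_t x_{t-j}^T] = C_j
    lags = [S[:k, j * k:(j + 1) * k].copy() for j in range(min(p, q + 1))]
    lags[0] = (lags[0] + lags[0].T) / 2
    while len(lags) < q + 1:
        j = len(lags)
        acc = np.zeros((k, k))
        for i in range(1, p + 1):
            ci = lags[j - i] if j - i >= 0 else lags[i - j].T
            acc += model.coeffs[i - 1] @ ci
        lags.append(acc)
    return CovarianceSequence(lags)


# ---------------------------------------------------------------------------
# Synthetic latent-variable model generator
# ---------------------------------------------------------------------------

def _default_positions(KS: int, K: int, seed) -> list[tuple[int, int]]:
    low = list(zip(*np.tril_indices(K, k=-1)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(low), size=KS, replace=False)
    return [(int(low[i][0]), int(low[i][1])) for i in sorted(idx)]


def generate_synthetic_model(KS: int, K: int = 15, r: int = 1, p: int = 1,
                             scale: float = 1.0, seed=0,
                             positions=None,
                             freq_grid: int = DEFAULT_FREQ_GRID,
                             pd_tol: float = 1e-8):
    """Build the latent-variable study model and its true pattern.

    The full ``(K+r)``-dimensional ISDM coefficients ``Q_0..Q_p`` have unit
    diagonals; ``KS`` below-diagonal manifest cells (and their symmetric
    counterparts) are set to ``scale * 0.5/(i+1)``; the latent couplings on
    the last ``r`` rows/columns are ``scale * 0.3/(i+1)``.  Multiples of the
    identity are added to ``Q_0`` until the polynomial is positive definite
    on a dense frequency grid, and the result is spectrally factorized into
    a stable VAR model.

    Returns ``(model, pattern, isdm)`` where ``pattern`` is the true
    manifest sparsity pattern and ``isdm`` the constructed polynomial.
    """
    K_bar = K * (K - 1) // 2
    if not 0 <= KS <= K_bar:
        raise ValueError(f"KS must be in 0..{K_bar}")
    kappa = K + r
    if positions is None:
        positions = _default_positions(KS, K, seed)
    elif len(positions) != KS:
        raise ValueError("positions length must equal KS")

    Q = [np.eye(kappa) for _ in range(p + 1)]
    for i in range(p + 1):
        for (a, b) in positions:
            Q[i][a, b] = Q[i][b, a] = scale * 0.5 / (i + 1)
        for a in range(kappa - r, kappa):
            for b in range(kappa):
                if a != b:
                    Q[i][a, b] = Q[i][b, a] = scale * 0.3 / (i + 1)

    isdm = TrigMatrixPolynomial([q.copy() for q in Q], block_sizes=(K, r))
    while isdm.min_eigenvalue(freq_grid) <= pd_tol:
        Q[0] = Q[0] + np.eye(kappa)
        isdm = TrigMatrixPolynomial([q.copy() for q in Q],
                                    block_sizes=(K, r))

    from .specfact import spectral_factorize

    factor = spectral_factorize(isdm)
    model = VARModel(factor.ar_coeffs, factor.sigma)
    pattern = SparsityPattern.from_edges(K, positions)
    return model, pattern, isdm
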