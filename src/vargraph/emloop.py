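"""The maximum-entropy EM sweep for latent-variable graphical VAR models.

For each penalty value ``lambda`` on a grid, the algorithm alternates an
expectation step — completing the sample covariances of the manifest
variables with the latent blocks implied by the current latent-manifest
ISDM polynomial — with a maximization step solving the penalized
maximum-entropy program (``solve_me2``).  The resulting ISDM is reduced to
a sparsity pattern by thresholding the maximum partial spectral coherence
over frequency, and the pattern is refined by a second, constrained loop
(``solve_me3``).  Spectral factorization of the final ISDM yields a
manifest VAR model whose residual covariance feeds the model-selection
criteria; the candidate minimizing the configured criterion wins.

The adaptive variant carries the latent-manifest estimate from one
``lambda`` to the next instead of re-initializing from the eigenvalue
decomposition, which markedly stabilizes the sweep.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import selection
from .maxent import SolverError, solve_me1, solve_me2, solve_me3
from .specfact import manifest_truncate, residual_covariance, spectral_factorize
from .varsim import (DEFAULT_FREQ_GRID, CovarianceSequence, SparsityPattern,
                     TimeSeries, TrigMatrixPolynomial, omega_grid,
                     sample_covariances)

logger = logging.getLogger(__name__)

__all__ = ["AlgoEMConfig", "CandidateModel", "AlgoEMRun",
           "init_latent_from_eig", "expectation_step", "max_psc",
           "extract_pattern", "run_algoem", "default_lambda_grid"]


def default_lambda_grid(lam_min: float = 1e-3, lam_max: float = 1e-1,
                        step: float = 1e-3) -> np.ndarray:
    """Regular penalty grid; the study default is [1e-3, 1e-1], step 1e-3."""
    n = int(round((lam_max - lam_min) / step)) + 1
    return lam_min + step * np.arange(n)


@dataclass
class AlgoEMConfig:
    """Settings for one EM sweep."""

    p: int = 1
    r: int = 1
    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    n_it: int = 2
    threshold: float = 1e-3
    adaptive: bool = True
    freq_grid: int = DEFAULT_FREQ_GRID
    criterion: str = "RNMLFD"
    gamma: float = 1.0
    bartlett_window: int | None = None
    score_penalized: bool = False
    skip_constrained: bool = False
    compute_scores: bool = True
    solver_options: dict = field(default_factory=dict)

    def __post_init__(self):
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0:
            raise ValueError("lambda_grid must be a nonempty 1-d array")
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("lambda_grid must be positive and ascending")
        self.lambda_grid = grid
        if self.n_it < 1:
            raise ValueError("n_it must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class CandidateModel:
    """Output of the EM sweep for one penalty value."""

    lam: float
    pattern: SparsityPattern | None = None
    isdm: TrigMatrixPolynomial | None = None
    isdm_penalized: TrigMatrixPolynomial | None = None
    manifest_coeffs: list | None = None
    sigma_hat: np.ndarray | None = None
    n_ef: int | None = None
    scores: dict = field(default_factory=dict)
    scores_penalized: dict = field(default_factory=dict)
    failed: bool = False
    message: str = ""

    @property
    def N0(self):
        return None if self.pattern is None else self.pattern.N0


def init_latent_from_eig(Q0_manifest: np.ndarray, r: int) -> np.ndarray:
    """Initial latent-manifest coupling from the eigenvalue decomposition.

    Eigen-decomposing the manifest lag-zero ISDM coefficient with
    eigenvalues sorted by decreasing magnitude, the coupling is
    ``D^{1/2}(1:r,1:r) U(:,1:r)^T`` (an ``r x K`` matrix).
    """
    Q0 = np.asarray(Q0_manifest, float)
    K = Q0.shape[0]
    if r > K:
        raise ValueError("r cannot exceed the number of manifest variables")
    w, U = np.linalg.eigh((Q0 + Q0.T) / 2)
    order = np.argsort(-np.abs(w))
    w, U = w[order], U[:, order]
    return np.sqrt(np.clip(w[:r], 0.0, None))[:, None] * U[:, :r].T


def expectation_step(R_hat: CovarianceSequence, Q_lm: dict,
                     p: int) -> CovarianceSequence:
    """Complete the manifest covariances with latent blocks.

    ``Q_lm`` maps lag indices ``-p..p`` to the ``r x K`` latent-manifest
    ISDM coefficients.  The latent-manifest covariance polynomial is the
    (negated) convolution of the coupling with the manifest spectrum,
    computed to degree ``2p``; the latent block is ``I`` plus a further
    convolution, truncated back to degree ``p``.
    """
    K = R_hat.dim
    r = np.asarray(Q_lm[0]).shape[0]
    for i in range(-p, p + 1):
        if i not in Q_lm:
            raise ValueError(f"Q_lm missing index {i}")
        if np.asarray(Q_lm[i]).shape != (r, K):
            raise ValueError("Q_lm blocks must be r x K")

    def R(i):
        return R_hat.lag(i) if abs(i) <= R_hat.q else None

    C_lm = {}
    for i in range(-2 * p, 2 * p + 1):
        acc = np.zeros((r, K))
        for k in range(max(-p, i - p), min(p, i + p) + 1):
            acc -= np.asarray(Q_lm[k]) @ R(i - k)
        C_lm[i] = acc
    # latent block: I + Ups_lm Phi_m Ups_lm^T(-w) = I - C_lm(w) Ups_lm^T(-w),
    # truncated back to degree p
    C_l = {}
    for i in range(-p, p + 1):
        acc = np.eye(r) if i == 0 else np.zeros((r, r))
        for k in range(max(-2 * p, i - p), min(2 * p, i + p) + 1):
            acc = acc - C_lm[k] @ np.asarray(Q_lm[k - i]).T
        C_l[i] = acc
    lags = []
    for i in range(p + 1):
        top = np.hstack([R(i), C_lm[-i].T])
        bot = np.hstack([C_lm[i], C_l[i]])
        lags.append(np.vstack([top, bot]))
    return CovarianceSequence(lags)


def _psc_matrix(isdm: TrigMatrixPolynomial, K: int,
                freq_grid: int) -> np.ndarray:
    """Max-over-frequency partial spectral coherence for all manifest pairs."""
    vals = isdm.evaluate(omega_grid(freq_grid))[:, :K, :K]
    diag = np.real(np.einsum("naa->na", vals))
    if diag.min() <= 0:
        raise ValueError("ISDM is not positive definite on the grid")
    denom = np.sqrt(diag[:, :, None] * diag[:, None, :])
    psc = np.abs(vals) / denom
    return psc.max(axis=0)


def max_psc(isdm: TrigMatrixPolynomial, a: int, b: int,
            freq_grid: int = DEFAULT_FREQ_GRID) -> float:
    """Maximum partial spectral coherence of one pair (0-based indices)."""
    if a == b:
        raise ValueError("PSC is defined for distinct variables")
    K = isdm.block_sizes[0] if isdm.block_sizes else isdm.dim
    if not (0 <= a < K and 0 <= b < K):
        raise ValueError("indices out of the manifest range")
    return float(_psc_matrix(isdm, K, freq_grid)[a, b])


def extract_pattern(isdm: TrigMatrixPolynomial, threshold: float, K: int,
                    freq_grid: int = DEFAULT_FREQ_GRID) -> SparsityPattern:
    """Pattern with an edge wherever the max PSC exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    psc = _psc_matrix(isdm, K, freq_grid)
    adj = psc > threshold
    adj = adj | adj.T
    np.fill_diagonal(adj, True)
    return SparsityPattern(adj)


def _lm_blocks(sol, K: int, p: int) -> dict:
    """Latent-manifest coefficient blocks of a block-parameter solution."""
    out = {}
    for i in range(p + 1):
        Di = sol.D(i)
        out[i] = Di[K:, :K].copy()
        out[-i] = Di[:K, K:].T.copy()
    return out


def _zero_lm(G0: np.ndarray, p: int) -> dict:
    r, K = G0.shape
    out = {0: G0}
    for i in range(1, p + 1):
        out[i] = np.zeros((r, K))
        out[-i] = np.zeros((r, K))
    return out


@dataclass
class AlgoEMRun:
    """Candidates of one sweep plus the winning index per selector."""

    candidates: list
    selected: dict
    config: AlgoEMConfig
    criterion: str
    selected_penalized: dict = field(default_factory=dict)

    @property
    def winner(self) -> CandidateModel:
        return self.candidates[self.selected[self.criterion]]

    def min_distance_to(self, truth: SparsityPattern) -> int:
        from .varsim import pattern_distance
        dists = [pattern_distance(c.pattern, truth)
                 for c in self.candidates if not c.failed]
        if not dists:
            raise RuntimeError("no successful candidates")
        return int(min(dists))

    def scores_frame(self, stage: str = "constrained"):
        import pandas as pd
        rows = []
        for c in self.candidates:
            sc = c.scores_penalized if stage == "penalized" else c.scores
            for name, value in sc.items():
                rows.append(dict(lam=c.lam, criterion=name, value=value,
                                 N0=c.N0, Nef=c.n_ef))
        return pd.DataFrame(rows)


def _em_inner(R_hat, Q_lm, lam_or_pattern, K, r, p, n_it, solver_opts,
              penalized: bool, warm=None):
    """Run Nit expectation/maximization alternations; returns (sol, Q_lm).

    ``warm`` seeds the first maximization from a previous solution of the
    same problem family (initialization only; the programs are convex, so
    the solutions are unchanged up to solver tolerance).
    """
    sol = None
    for _ in range(n_it):
        C = expectation_step(R_hat, Q_lm, p)
        opts = solver_opts if warm is None else {"t0": 100.0, **solver_opts}
        if penalized:
            sol = solve_me2(C, lam_or_pattern, K, r, warm=warm, **opts)
        else:
            sol = solve_me3(C, lam_or_pattern, K, r, warm=warm, **opts)
        warm = sol._z
        Q_lm = _lm_blocks(sol, K, p)
    return sol, Q_lm


def run_algoem(series: TimeSeries, config: AlgoEMConfig,
               true_pattern: SparsityPattern | None = None) -> AlgoEMRun:
    """Full EM sweep over the penalty grid.

    Returns one candidate per grid value (failed solves are flagged and
    excluded from selection) and the argmin index for every selector.
    When ``true_pattern`` is given an ``oracle`` selector (closest pattern
    in the candidate set) is included.
    """
    K = series.dim
    p, r = config.p, config.r
    T = series.T
    if T < K * (p + 1):
        raise ValueError("series too short for covariance estimation")
    opts = dict(config.solver_options)

    R_hat = sample_covariances(series, p)
    me1 = solve_me1(R_hat, **opts)
    G0 = init_latent_from_eig(me1.D(0), r)
    Q_lm_init = _zero_lm(G0, p)

    correlogram_evals = None
    if config.compute_scores:
        _, correlogram_evals = selection.correlogram_bartlett(
            series, config.bartlett_window, config.freq_grid)
    grid_omega = omega_grid(config.freq_grid)

    candidates = []
    Q_lm_carry = Q_lm_init
    warm_carry = None
    for idx, lam in enumerate(config.lambda_grid):
        cand = CandidateModel(lam=float(lam))
        Q_lm0 = Q_lm_carry if (config.adaptive and idx > 0) else Q_lm_init
        try:
            sol, Q_lm = _em_inner(R_hat, Q_lm0, float(lam), K, r, p,
                                  config.n_it, opts, penalized=True,
                                  warm=warm_carry)
            warm_carry = sol._z
            isdm_pen = TrigMatrixPolynomial(sol.isdm_coeffs(),
                                            block_sizes=(K, r))
            cand.isdm_penalized = isdm_pen
            cand.pattern = extract_pattern(isdm_pen, config.threshold, K,
                                           config.freq_grid)
            if config.adaptive:
                Q_lm_carry = Q_lm
            if not config.skip_constrained:
                sol3, _ = _em_inner(R_hat, Q_lm, cand.pattern, K, r, p,
                                    config.n_it, opts, penalized=False)
                cand.isdm = TrigMatrixPolynomial(sol3.isdm_coeffs(),
                                                 block_sizes=(K, r))
            else:
                cand.isdm = isdm_pen
            cand.n_ef = selection.effective_params(cand.pattern, p)
            if config.compute_scores:
                cand.scores, extras = _score_candidate(
                    series, cand.isdm, cand.pattern, R_hat, config,
                    correlogram_evals, grid_omega)
                cand.manifest_coeffs, cand.sigma_hat = extras
                if config.score_penalized and not config.skip_constrained:
                    cand.scores_penalized, _ = _score_candidate(
                        series, isdm_pen, cand.pattern, R_hat, config,
                        correlogram_evals, grid_omega)
        except (SolverError, ValueError, np.linalg.LinAlgError) as exc:
            cand.failed = True
            cand.message = str(exc)
            logger.warning("candidate lambda=%g failed: %s", lam, exc)
        candidates.append(cand)

    selected = _select(candidates, true_pattern)
    selected_pen = {}
    if config.score_penalized:
        selected_pen = _select(candidates, true_pattern,
                               attr="scores_penalized")
    return AlgoEMRun(candidates=candidates, selected=selected,
                     config=config, criterion=config.criterion,
                     selected_penalized=selected_pen)


def _score_candidate(series, isdm, pattern, R_hat, config,
                     correlogram_evals, grid_omega):
    K = pattern.K
    factor = spectral_factorize(isdm, config.freq_grid)
    mfac = manifest_truncate(factor, K)
    sigma_hat = residual_covariance(series, mfac.ar_coeffs)
    entropy_rate = None
    if correlogram_evals is not None:
        inv_spec = _manifest_inverse_spectrum(mfac.ar_coeffs, sigma_hat,
                                              grid_omega)
        try:
            entropy_rate = selection.relative_entropy_rate(
                correlogram_evals, den_inverse=inv_spec,
                freq_grid=config.freq_grid)
        except ValueError:
            entropy_rate = None
    scores = selection.score_all_criteria(
        sigma_hat, R_hat.lag(0), pattern, config.p, series.T,
        gamma=config.gamma, entropy_rate=entropy_rate, r=config.r)
    return scores, (mfac.ar_coeffs, sigma_hat)


def _manifest_inverse_spectrum(ar_coeffs, sigma, omegas):
    """``A(w)^H Sigma^{-1} A(w)`` evaluations of a fitted VAR model."""
    K = sigma.shape[0]
    p = len(ar_coeffs)
    A = np.tile(-np.eye(K, dtype=complex), (len(omegas), 1, 1))
    for i, a in enumerate(ar_coeffs, start=1):
        phase = np.exp(-1j * omegas * i)
        A += phase[:, None, None] * np.asarray(a)
    A = -A  # A(w) = -(A_0 + sum A_i e^{-jwi}) with A_0 = -I
    Sinv = np.linalg.inv(sigma)
    return np.swapaxes(A.conj(), -1, -2) @ Sinv @ A


def _select(candidates, true_pattern, attr="scores"):
    from .varsim import pattern_distance
    ok = [i for i, c in enumerate(candidates) if not c.failed]
    selected = {}
    names = set()
    for i in ok:
        names.update(getattr(candidates[i], attr))
    for name in sorted(names):
        best, best_val = None, math.inf
        for i in ok:
            v = getattr(candidates[i], attr).get(name, math.nan)
            if v is not None and not math.isnan(v) and v < best_val:
                best, best_val = i, v
        if best is not None:
            selected[name] = best
    if true_pattern is not None and ok:
        dists = [(pattern_distance(candidates[i].pattern, true_pattern), i)
                 for i in ok]
        selected["oracle"] = min(dists)[1]
    return selected
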