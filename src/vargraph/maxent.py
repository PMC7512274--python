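"""Maximum-entropy convex programs for ISDM estimation.

Three related log-det semidefinite programs are solved over a symmetric
block-parameter matrix ``X`` of size ``m(p+1)``, whose block traces
``D_i(X)`` are the ISDM polynomial coefficients:

* ``solve_me1`` — the classical maximum-entropy VAR problem on manifest
  sample covariances (no latent variables, no penalty); its solution
  coincides with the Yule–Walker fit.
* ``solve_me2`` — the penalized full-model problem with the group
  sparsity promoter ``f`` on manifest off-diagonal entries and equality
  constraints fixing the latent block of the ISDM to the identity.
* ``solve_me3`` — as ``solve_me2`` with the penalty replaced by hard
  zeros on the entries excluded by a given sparsity pattern.

``solve_sparse_lowrank`` implements the sparse-plus-low-rank comparison
program over manifest covariances only, decomposing the manifest ISDM
into ``Delta (X) Delta^H`` with a low-rank correction ``Delta L Delta^H``
penalized through its trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._solver import SDPProblem, SolverError, solve_sdp, svec
from .varsim import (CovarianceSequence, SparsityPattern, block_toeplitz,
                     block_trace)

__all__ = ["BlockParamMatrix", "sparsity_promoter", "solve_me1",
           "solve_me2", "solve_me3", "solve_sparse_lowrank", "SolverError"]

SQRT2 = np.sqrt(2.0)


@dataclass
class BlockParamMatrix:
    """PSD optimization variable with block-trace accessors."""

    value: np.ndarray
    block: int
    order: int
    objective: float = field(default=np.nan)
    gap: float = field(default=np.nan)
    status: str = field(default="")

    def D(self, i: int) -> np.ndarray:
        """Block trace ``D_i``; negative indices via transposition."""
        if i < 0:
            return block_trace(self.value, -i, self.block).T
        return block_trace(self.value, i, self.block)

    def isdm_coeffs(self) -> list[np.ndarray]:
        return [self.D(i) for i in range(self.order + 1)]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.value)[0])


def sparsity_promoter(Z, K: int, order: int | None = None,
                      block: int | None = None) -> float:
    """Group sparsity promoter ``f(Z) = sum_{a>b<=K} max_i |D_i(Z)(a,b)|``.

    For ``i >= 1`` both ``D_i(a, b)`` and ``D_i(b, a)`` enter the max:
    they are the two independent coefficients of the ``(a, b)``
    off-diagonal ISDM polynomial (``Q_{-i}(a,b) = Q_i(b,a)``), so the
    group must cover both for the penalty to promote conditional
    independence.
    """
    if isinstance(Z, BlockParamMatrix):
        M, m, p = Z.value, Z.block, Z.order
    else:
        M = np.asarray(Z, float)
        if block is None or order is None:
            raise ValueError("block and order required for raw arrays")
        m, p = block, order
    D = [block_trace(M, i, m) for i in range(p + 1)]
    total = 0.0
    for a in range(1, K):
        for b in range(a):
            vals = [abs(D[0][a, b])]
            for i in range(1, p + 1):
                vals += [abs(D[i][a, b]), abs(D[i][b, a])]
            total += max(vals)
    return float(total)


# ---------------------------------------------------------------------------
# Functional builders (svec indexing of block-trace entries)
# ---------------------------------------------------------------------------

def _svec_k(i: int, j: int) -> int:
    a, b = (i, j) if i >= j else (j, i)
    return a * (a + 1) // 2 + b


def _entry_functional(m: int, p: int, i: int, a: int, b: int,
                      offset: int = 0):
    """Sparse functional for ``D_i(X)(a, b)`` over svec(X)."""
    acc: dict[int, float] = {}
    for h in range(p + 1 - i):
        r, c = h * m + a, (h + i) * m + b
        k = offset + _svec_k(r, c)
        acc[k] = acc.get(k, 0.0) + (1.0 if r == c else 1.0 / SQRT2)
    idx = np.fromiter(acc.keys(), dtype=int)
    coef = np.fromiter(acc.values(), dtype=float)
    return idx, coef


def _pair_group(m: int, p: int, a: int, b: int, weight: float,
                offsets=(0,)):
    # one functional per independent coefficient of the (a, b) polynomial:
    # D_0(a,b), then D_i(a,b) and D_i(b,a) for i >= 1
    cells = [(0, a, b)]
    for i in range(1, p + 1):
        cells += [(i, a, b), (i, b, a)]
    funcs = []
    for i, aa, bb in cells:
        parts_idx, parts_coef = [], []
        for off in offsets:
            idx, coef = _entry_functional(m, p, i, aa, bb, off)
            parts_idx.append(idx)
            parts_coef.append(coef)
        funcs.append((np.concatenate(parts_idx), np.concatenate(parts_coef)))
    return (weight, funcs)


def _manifest_groups(m: int, p: int, K: int, weight: float, offsets=(0,)):
    return [_pair_group(m, p, a, b, weight, offsets)
            for a in range(1, K) for b in range(a)]


def _row(N: int, idx, coef) -> np.ndarray:
    row = np.zeros(N)
    row[idx] += coef
    return row


def _latent_equalities(m: int, p: int, K: int, r: int, nsvec: int):
    """Rows fixing ``D_0`` latent block to I and ``D_i`` (i>=1) to 0."""
    rows, rhs = [], []
    for a in range(K, m):
        for b in range(K, a + 1):
            idx, coef = _entry_functional(m, p, 0, a, b)
            rows.append(_row(nsvec, idx, coef))
            rhs.append(1.0 if a == b else 0.0)
    for i in range(1, p + 1):
        for a in range(K, m):
            for b in range(K, m):
                idx, coef = _entry_functional(m, p, i, a, b)
                rows.append(_row(nsvec, idx, coef))
                rhs.append(0.0)
    return rows, rhs


def _scaled_identity_start(prob: SDPProblem, scale_blocks) -> np.ndarray:
    z = np.zeros(prob.N)
    for b, c in zip(prob.blocks, scale_blocks):
        z[b.offset:b.offset + b.nv] = svec(c * np.eye(b.n))
    if prob.n_f:
        u = np.abs(prob.U @ z)
        smax = np.zeros(prob.n_groups)
        np.maximum.at(smax, prob.gmap, u)
        z[prob.n_matvar:] = smax + 1.0
    return z


def _check_toeplitz(cov: CovarianceSequence) -> np.ndarray:
    Tm = block_toeplitz(cov)
    if np.linalg.eigvalsh(Tm)[0] <= 0:
        raise SolverError(
            "block-Toeplitz covariance embedding is not positive definite; "
            "the maximum-entropy problem is unbounded",
            status="indefinite_input")
    return Tm


def _wrap(prob: SDPProblem, res, m: int, p: int,
          block_index: int = 0) -> BlockParamMatrix:
    return BlockParamMatrix(value=res.blocks[block_index], block=m, order=p,
                            objective=res.objective, gap=res.gap,
                            status=res.status)


_DEFAULT_OPTS = dict(gap_tol=1e-6, mu=10.0)


def solve_me1(cov: CovarianceSequence, warm=None,
              **options) -> BlockParamMatrix:
    """Classical maximum-entropy problem on manifest covariances.

    Minimizes ``tr(T(R) X) - logdet X00`` over PSD ``X``; the ISDM
    coefficient estimates are ``D_i(X)``.
    """
    m, p = cov.dim, cov.q
    Tm = _check_toeplitz(cov)
    prob = SDPProblem(block_sizes=[m * (p + 1)], costs=[Tm], logdet_dim=m)
    prob.start = _scaled_identity_start(prob, [1.0 / (p + 1)])
    opts = {**_DEFAULT_OPTS, **options}
    z0 = warm if warm is not None else prob.start
    res = solve_sdp(prob, z0=z0, **opts)
    out = _wrap(prob, res, m, p)
    out._z = res.z
    return out


def _me_problem(cov: CovarianceSequence, lam: float, K: int, r: int,
                pattern: SparsityPattern | None):
    m, p = cov.dim, cov.q
    if m != K + r:
        raise ValueError(f"covariances are {m}-dimensional, expected K+r={K + r}")
    Tm = block_toeplitz(cov)
    n = m * (p + 1)
    nsvec = n * (n + 1) // 2
    groups = _manifest_groups(m, p, K, lam) if lam > 0 else []
    rows, rhs = _latent_equalities(m, p, K, r, nsvec)
    if pattern is not None:
        adj = pattern.adjacency
        for a in range(1, K):
            for b in range(a):
                if adj[a, b]:
                    continue
                idx, coef = _entry_functional(m, p, 0, a, b)
                rows.append(_row(nsvec, idx, coef))
                rhs.append(0.0)
                for i in range(1, p + 1):
                    for (aa, bb) in ((a, b), (b, a)):
                        idx, coef = _entry_functional(m, p, i, aa, bb)
                        rows.append(_row(nsvec, idx, coef))
                        rhs.append(0.0)
    prob = SDPProblem(block_sizes=[n], costs=[Tm], logdet_dim=m,
                      groups=groups, equalities=(np.vstack(rows), rhs))
    prob.start = _scaled_identity_start(prob, [1.0 / (p + 1)])
    return prob, m, p


def solve_me2(cov: CovarianceSequence, lam: float, K: int, r: int,
              warm=None, **options) -> BlockParamMatrix:
    """Penalized full-model maximum-entropy problem.

    Adds ``lam * f(X)`` on manifest off-diagonal entries and constrains the
    latent block of the ISDM to the identity (latent variables have unit
    variance and are conditionally independent given the manifest ones).
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    prob, m, p = _me_problem(cov, lam, K, r, None)
    opts = {**_DEFAULT_OPTS, **options}
    z0 = warm if warm is not None else prob.start
    res = solve_sdp(prob, z0=z0, **opts)
    out = _wrap(prob, res, m, p)
    out._z = res.z
    return out


def solve_me3(cov: CovarianceSequence, sp: SparsityPattern, K: int, r: int,
              warm=None, **options) -> BlockParamMatrix:
    """Constrained maximum-entropy problem: hard zeros outside the pattern."""
    if sp.K != K:
        raise ValueError("pattern size must equal K")
    prob, m, p = _me_problem(cov, 0.0, K, r, sp)
    opts = {**_DEFAULT_OPTS, **options}
    z0 = warm if warm is not None else prob.start
    res = solve_sdp(prob, z0=z0, **opts)
    out = _wrap(prob, res, m, p)
    out._z = res.z
    return out


def solve_sparse_lowrank(cov: CovarianceSequence, lam: float, gamma: float,
                         warm=None, **options):
    """Sparse-plus-low-rank program on manifest covariances.

    Minimizes ``tr(T(R) X) - logdet X00 + lam*gamma*f(X+L) + lam*tr(L)``
    over PSD ``X`` and ``L``.  Returns ``(X, L)``.
    """
    if lam <= 0 or gamma <= 0:
        raise ValueError("lam and gamma must be positive")
    K, p = cov.dim, cov.q
    Tm = _check_toeplitz(cov)
    n = K * (p + 1)
    nsvec = n * (n + 1) // 2
    groups = _manifest_groups(K, p, K, lam * gamma, offsets=(0, nsvec))
    prob = SDPProblem(block_sizes=[n, n], costs=[Tm, lam * np.eye(n)],
                      logdet_dim=K, groups=groups)
    prob.start = _scaled_identity_start(prob, [1.0 / (p + 1), 0.1])
    opts = {**_DEFAULT_OPTS, **options}
    z0 = warm if warm is not None else prob.start
    res = solve_sdp(prob, z0=z0, **opts)
    X = _wrap(prob, res, K, p, 0)
    L = _wrap(prob, res, K, p, 1)
    X._z = res.z
    return X, L
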