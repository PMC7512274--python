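"""Path-following barrier solver for log-det semidefinite programs.

Solves problems of the form

    minimize    sum_b <T_b, X_b>  -  logdet (X_0)[:d, :d]  +  sum_g w_g s_g
    subject to  X_b >= 0  (PSD),
                |u_{g,i}(z)| <= s_g   for every functional i of group g,
                A z = b,

where each ``X_b`` is a symmetric matrix variable, ``z`` stacks the
scaled lower-triangle vectorization (svec) of all blocks followed by the
epigraph slacks ``s``, and the ``u_{g,i}`` are sparse linear functionals
(block-trace entries).  The group terms implement an L1-of-Linf penalty in
epigraph form; the hard-zero variants use equality rows of ``A`` instead.

The implementation is a standard feasible-start Newton barrier method:
for increasing ``t`` minimize ``t * f0(z) + phi(z)`` where ``phi`` is the
log barrier of all conic and linear inequality constraints, with equality
constraints handled through the KKT system.  The suboptimality after the
final stage is bounded by ``nu / t`` with ``nu`` the total barrier
parameter, which is reported as ``gap``.

All problems in this package are small (matrix sides below ~70), so dense
linear algebra is used throughout; the Hessian of a log-det term in svec
coordinates is assembled by vectorized indexing of the inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import linalg as sla

__all__ = ["SDPProblem", "SolverError", "SolverResult", "solve_sdp"]

SQRT2 = np.sqrt(2.0)


class SolverError(RuntimeError):
    def __init__(self, message, status="failed"):
        super().__init__(message)
        self.status = status


@dataclass
class _BlockInfo:
    n: int
    offset: int
    I: np.ndarray
    J: np.ndarray
    W: np.ndarray

    @property
    def nv(self) -> int:
        return self.I.size

    def gather_indices(self):
        """Flat index tables for the log-det Hessian (built lazily)."""
        if not hasattr(self, "_fII"):
            n, I, J = self.n, self.I, self.J
            self._fII = I[:, None] * n + I[None, :]
            self._fJJ = J[:, None] * n + J[None, :]
            self._fIJ = I[:, None] * n + J[None, :]
            self._fJI = J[:, None] * n + I[None, :]
            self._WW = 0.5 * np.outer(self.W, self.W)
        return self._fII, self._fJJ, self._fIJ, self._fJI, self._WW


def _block_info(n: int, offset: int) -> _BlockInfo:
    I, J = np.tril_indices(n)
    W = np.where(I == J, 1.0, SQRT2)
    return _BlockInfo(n=n, offset=offset, I=I, J=J, W=W)


def svec(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    I, J = np.tril_indices(n)
    W = np.where(I == J, 1.0, SQRT2)
    return W * M[I, J]


def unsvec(v: np.ndarray, n: int) -> np.ndarray:
    I, J = np.tril_indices(n)
    W = np.where(I == J, 1.0, SQRT2)
    M = np.zeros((n, n))
    M[I, J] = v / W
    M[J, I] = M[I, J]
    return M


def _logdet_hess(S: np.ndarray, I: np.ndarray, J: np.ndarray,
                 W: np.ndarray) -> np.ndarray:
    """Hessian of -logdet X in svec coordinates, given S = X^{-1}."""
    SII = S[np.ix_(I, I)]
    SJJ = S[np.ix_(J, J)]
    SIJ = S[np.ix_(I, J)]
    SJI = S[np.ix_(J, I)]
    H = 0.5 * (SII * SJJ + SIJ * SJI)
    return H * np.outer(W, W)


def _logdet_hess_block(S: np.ndarray, info: _BlockInfo) -> np.ndarray:
    """Fast path of :func:`_logdet_hess` using cached flat indices."""
    fII, fJJ, fIJ, fJI, WW = info.gather_indices()
    Sf = np.ascontiguousarray(S).ravel()
    B1 = np.take(Sf, fII)
    np.multiply(B1, np.take(Sf, fJJ), out=B1)
    B2 = np.take(Sf, fIJ)
    np.multiply(B2, np.take(Sf, fJI), out=B2)
    np.add(B1, B2, out=B1)
    np.multiply(B1, WW, out=B1)
    return B1


@dataclass
class SDPProblem:
    """Problem data; see the module docstring for the template."""

    block_sizes: list[int]
    costs: list[np.ndarray]
    logdet_dim: int
    logdet_block: int = 0
    # groups: list of (weight, [functional, ...]); each functional is a
    # pair (idx, coef) of equal-length arrays over the joint z vector
    groups: list = field(default_factory=list)
    # equalities: (A, b) with A of shape (n_eq, N_z)  (z part only)
    equalities: tuple | None = None
    # optional caller-provided strictly feasible start
    start: np.ndarray | None = None

    def __post_init__(self):
        self.blocks = []
        off = 0
        for n in self.block_sizes:
            info = _block_info(n, off)
            self.blocks.append(info)
            off += info.nv
        self.n_matvar = off
        self.n_groups = len(self.groups)
        self.N = self.n_matvar + self.n_groups

        c = np.zeros(self.N)
        for info, T in zip(self.blocks, self.costs):
            c[info.offset:info.offset + info.nv] = svec(np.asarray(T, float))
        for g, (w, _) in enumerate(self.groups):
            c[self.n_matvar + g] = w
        self.c = c

        # stack functionals into a sparse matrix U (n_f x N)
        rows, cols, vals, gmap = [], [], [], []
        f = 0
        for g, (_, funcs) in enumerate(self.groups):
            for idx, coef in funcs:
                rows.extend([f] * len(idx))
                cols.extend(idx)
                vals.extend(coef)
                gmap.append(g)
                f += 1
        self.n_f = f
        if f:
            self.U = sp.csr_matrix(
                (vals, (rows, cols)), shape=(f, self.N))
            self.gmap = np.asarray(gmap)
        else:
            self.U = None
            self.gmap = np.zeros(0, dtype=int)

        if self.equalities is not None:
            A, b = self.equalities
            A = np.asarray(A, float)
            if A.shape[1] != self.N:
                A = np.hstack([A, np.zeros((A.shape[0],
                                            self.N - A.shape[1]))])
            self.A_eq, self.b_eq = A, np.asarray(b, float)
        else:
            self.A_eq, self.b_eq = None, None

        # indices of the logdet sub-block entries within the joint vector
        info = self.blocks[self.logdet_block]
        d = self.logdet_dim
        mask = (info.I < d) & (info.J < d)
        self.ld_pos = info.offset + np.nonzero(mask)[0]
        self.ld_I = info.I[mask]
        self.ld_J = info.J[mask]
        self.ld_W = info.W[mask]

        # barrier parameter
        self.nu = float(sum(self.block_sizes) + 2 * self.n_f)

    # -- helpers -------------------------------------------------------
    def mats(self, z: np.ndarray) -> list[np.ndarray]:
        return [unsvec(z[b.offset:b.offset + b.nv], b.n)
                for b in self.blocks]

    def slacks(self, z: np.ndarray):
        if not self.n_f:
            return None, None
        u = self.U @ z
        s = z[self.n_matvar + self.gmap]
        return s - u, s + u

    def default_start(self) -> np.ndarray:
        z = np.zeros(self.N)
        for b, T in zip(self.blocks, self.costs):
            X0 = np.eye(b.n)
            z[b.offset:b.offset + b.nv] = svec(X0)
        if self.n_f:
            u = np.abs(self.U @ z)
            smax = np.zeros(self.n_groups)
            np.maximum.at(smax, self.gmap, u)
            z[self.n_matvar:] = smax + 1.0
        return z


@dataclass
class SolverResult:
    blocks: list[np.ndarray]
    s: np.ndarray
    objective: float
    gap: float
    status: str
    newton_steps: int
    z: np.ndarray
    t: float


def _objective(prob: SDPProblem, z, X00=None):
    val = float(prob.c @ z)
    if X00 is None:
        info = prob.blocks[prob.logdet_block]
        X = unsvec(z[info.offset:info.offset + info.nv], info.n)
        X00 = X[:prob.logdet_dim, :prob.logdet_dim]
    sign, ld = np.linalg.slogdet(X00)
    if sign <= 0:
        return np.inf
    return val - ld


def _psi_and_chol(prob: SDPProblem, z, t):
    """Barrier-augmented objective; returns (psi, chols) or (inf, None)."""
    psi = t * float(prob.c @ z)
    chols = []
    for b in prob.blocks:
        X = unsvec(z[b.offset:b.offset + b.nv], b.n)
        try:
            L = np.linalg.cholesky(X)
        except np.linalg.LinAlgError:
            return np.inf, None
        chols.append(L)
        psi -= 2.0 * np.log(np.diag(L)).sum()
    # objective's own logdet on the leading sub-block
    info = prob.blocks[prob.logdet_block]
    X = unsvec(z[info.offset:info.offset + info.nv], info.n)
    X00 = X[:prob.logdet_dim, :prob.logdet_dim]
    try:
        L00 = np.linalg.cholesky(X00)
    except np.linalg.LinAlgError:
        return np.inf, None
    psi -= t * 2.0 * np.log(np.diag(L00)).sum()
    cm, cp = prob.slacks(z)
    if cm is not None:
        if cm.min() <= 0 or cp.min() <= 0:
            return np.inf, None
        psi -= np.log(cm).sum() + np.log(cp).sum()
    return psi, (chols, L00)


def _grad_hess(prob: SDPProblem, z, t, chols):
    N = prob.N
    g = t * prob.c.copy()
    H = np.zeros((N, N))
    block_chols, L00 = chols
    for b, L in zip(prob.blocks, block_chols):
        S = sla.cho_solve((L, True), np.eye(b.n))
        sl = slice(b.offset, b.offset + b.nv)
        g[sl] -= b.W * S[b.I, b.J]
        H[sl, sl] += _logdet_hess_block(S, b)
    # -t * logdet X00 term
    S0 = sla.cho_solve((L00, True), np.eye(prob.logdet_dim))
    g[prob.ld_pos] -= t * prob.ld_W * S0[prob.ld_I, prob.ld_J]
    H[np.ix_(prob.ld_pos, prob.ld_pos)] += t * _logdet_hess(
        S0, prob.ld_I, prob.ld_J, prob.ld_W)
    # linear inequality barriers
    cm, cp = prob.slacks(z)
    if cm is not None:
        U = prob.U
        inv_m, inv_p = 1.0 / cm, 1.0 / cp
        # gradient: d/dz of -log(s-u)-log(s+u)
        g += U.T @ (inv_m - inv_p)
        gs = np.zeros(prob.n_groups)
        np.add.at(gs, prob.gmap, -(inv_m + inv_p))
        g[prob.n_matvar:] += gs
        w2 = inv_m ** 2 + inv_p ** 2
        Hxx = (U.T.multiply(w2) @ U).toarray()
        H[:, :] += Hxx  # U has zero columns on the s part
        cross = inv_p ** 2 - inv_m ** 2
        Hxs = (U.T @ sp.csr_matrix(
            (cross, (np.arange(prob.n_f), prob.gmap)),
            shape=(prob.n_f, prob.n_groups))).toarray()
        H[:, prob.n_matvar:] += Hxs
        H[prob.n_matvar:, :] += Hxs.T
        hss = np.zeros(prob.n_groups)
        np.add.at(hss, prob.gmap, w2)
        H[prob.n_matvar:, prob.n_matvar:] += np.diag(hss)
    return g, H


def _newton_step(prob: SDPProblem, g, H):
    ridge = 0.0
    for _ in range(6):
        try:
            Hr = H if ridge == 0 else H + ridge * np.eye(prob.N)
            cho = sla.cho_factor(Hr, check_finite=False)
            if prob.A_eq is None:
                dz = -sla.cho_solve(cho, g, check_finite=False)
                return dz
            A = prob.A_eq
            HiAt = sla.cho_solve(cho, A.T, check_finite=False)
            Hig = sla.cho_solve(cho, g, check_finite=False)
            Sm = A @ HiAt
            nu = np.linalg.solve(Sm, -A @ Hig)
            return -(Hig + HiAt @ nu)
        except np.linalg.LinAlgError:
            ridge = max(ridge * 100, 1e-10 * (1 + np.trace(H) / prob.N))
    raise SolverError("Newton system could not be solved",
                      status="numerical_failure")


def solve_sdp(prob: SDPProblem, z0=None, t0=10.0, mu=10.0,
              gap_tol=1e-6, newton_tol=1e-9, stage_tol=1e-5,
              max_newton_per_stage=60,
              max_total_newton=2000, trace=None) -> SolverResult:
    """Minimize the barrier problem; see module docstring.

    ``z0`` must be strictly feasible (PSD blocks, slack room, equalities
    satisfied); defaults to identity blocks.
    """
    z = prob.default_start() if z0 is None else np.asarray(z0, float).copy()

    def _eq_ok(zz):
        if prob.A_eq is None:
            return True
        return np.abs(prob.A_eq @ zz - prob.b_eq).max() <= 1e-8

    psi, chols = _psi_and_chol(prob, z, t0)
    if not np.isfinite(psi) or not _eq_ok(z):
        z = prob.start.copy() if prob.start is not None \
            else prob.default_start()
        psi, chols = _psi_and_chol(prob, z, t0)
        if not np.isfinite(psi):
            raise SolverError("no strictly feasible starting point",
                              status="infeasible_start")
        if not _eq_ok(z):
            raise SolverError(
                "starting point violates the equality constraints",
                status="infeasible_start")

    t = float(t0)
    total_steps = 0
    while True:
        # center at this t; intermediate stages are centered loosely
        final_stage = prob.nu / t < gap_tol
        tol = newton_tol if final_stage else stage_tol
        for _ in range(max_newton_per_stage):
            g, H = _grad_hess(prob, z, t, chols)
            dz = _newton_step(prob, g, H)
            lam2 = float(-g @ dz)
            if lam2 < 0:  # numerical loss of descent; tiny step to bail out
                break
            if lam2 / 2.0 <= tol:
                break
            # maximum step keeping linear slacks positive
            alpha = 1.0
            if prob.n_f:
                cm, cp = prob.slacks(z)
                du = prob.U @ dz
                ds = dz[prob.n_matvar + prob.gmap]
                dm, dp = ds - du, ds + du
                bad = dm < 0
                if bad.any():
                    alpha = min(alpha, 0.99 * float((cm[bad] / -dm[bad]).min()))
                bad = dp < 0
                if bad.any():
                    alpha = min(alpha, 0.99 * float((cp[bad] / -dp[bad]).min()))
            # backtracking on psi (also enforces PSD via cholesky)
            ok = False
            for _bt in range(40):
                z_new = z + alpha * dz
                psi_new, chols_new = _psi_and_chol(prob, z_new, t)
                if psi_new <= psi - 0.01 * alpha * lam2:
                    ok = True
                    break
                alpha *= 0.5
            total_steps += 1
            if not ok or total_steps >= max_total_newton:
                break
            z, psi, chols = z_new, psi_new, chols_new
        if trace is not None:
            trace.append((t, total_steps))
        if prob.nu / t < gap_tol:
            break
        if total_steps >= max_total_newton:
            raise SolverError(
                f"Newton budget exhausted at t={t:.1e}",
                status="max_iterations")
        t *= mu
        psi, chols = _psi_and_chol(prob, z, t)

    mats = prob.mats(z)
    return SolverResult(
        blocks=mats,
        s=z[prob.n_matvar:].copy(),
        objective=_objective(prob, z),
        gap=prob.nu / t,
        status="optimal",
        newton_steps=total_steps,
        z=z,
        t=t,
    )
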