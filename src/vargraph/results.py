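"""Results objects returned by the model classes."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import specfact
from .varsim import SparsityPattern, VARModel, pattern_distance

__all__ = ["LatentGraphicalVARResults", "SparseLowRankVARResults"]


class LatentGraphicalVARResults:
    """Candidate set and selected model of a maximum-entropy EM sweep.

    Attributes
    ----------
    candidates : list of CandidateModel
        One entry per penalty value (failed solves flagged).
    selected : dict
        Winning candidate index per selector name.
    criterion : str
        The selector used by :attr:`winner` and :meth:`summary`.
    """

    def __init__(self, model, run):
        self.model = model
        self.run = run
        self.candidates = run.candidates
        self.selected = run.selected
        self.criterion = run.criterion

    # -- winner accessors ---------------------------------------------
    @property
    def winner(self):
        if self.criterion not in self.selected:
            raise RuntimeError(
                f"criterion {self.criterion!r} selected no candidate")
        return self.candidates[self.selected[self.criterion]]

    @property
    def pattern(self) -> SparsityPattern:
        return self.winner.pattern

    @property
    def lam(self) -> float:
        return self.winner.lam

    @property
    def sigma_hat(self):
        return self.winner.sigma_hat

    @property
    def n_ef(self):
        return self.winner.n_ef

    def manifest_var(self) -> VARModel:
        """Fitted manifest VAR model of the winning candidate."""
        w = self.winner
        if w.manifest_coeffs is None:
            raise RuntimeError("scores were not computed for this run")
        return VARModel(w.manifest_coeffs, w.sigma_hat)

    def min_distance_to(self, truth: SparsityPattern) -> int:
        return self.run.min_distance_to(truth)

    def distance_to(self, truth: SparsityPattern,
                    selector: str | None = None) -> int:
        name = selector or self.criterion
        return pattern_distance(
            self.candidates[self.selected[name]].pattern, truth)

    # -- tables and export --------------------------------------------
    def scores_frame(self, stage: str = "constrained") -> pd.DataFrame:
        """Tidy table: one row per (lambda, criterion)."""
        return self.run.scores_frame(stage)

    def candidates_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.candidates):
            row = dict(index=i, lam=c.lam, failed=c.failed,
                       N0=c.N0, Nef=c.n_ef)
            for k, v in c.scores.items():
                row[k] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        doc = {
            "criterion": self.criterion,
            "selected": {k: int(v) for k, v in self.selected.items()},
            "candidates": [
                {"lam": c.lam, "failed": c.failed, "N0": c.N0,
                 "Nef": c.n_ef,
                 "scores": {k: (None if v is None or (
                     isinstance(v, float) and np.isnan(v)) else float(v))
                     for k, v in c.scores.items()}}
                for c in self.candidates],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def save_pattern(self, matrix_path=None, edges_path=None) -> None:
        """Write the winning pattern as a 0/1 matrix and an edge list."""
        pat = self.pattern
        if matrix_path is not None:
            with open(matrix_path, "w") as fh:
                fh.write(pat.to_text() + "\n")
        if edges_path is not None:
            names = self.model.series.names
            with open(edges_path, "w") as fh:
                for a, b in pat.edges():
                    fh.write(f"{names[a]}\t{names[b]}\n")

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        m = self.model
        w = self.winner
        K = m.K
        lines = []
        add = lines.append
        add("Latent-variable graphical VAR model")
        add("=" * 51)
        add(f"No. observations: {m.series.T:>10}   VAR order p: {m.order:>6}")
        add(f"Manifest vars K:  {K:>10}   Latent vars r: {m.n_latent:>4}")
        add(f"Penalty grid:     {len(self.candidates):>10} values in "
            f"[{self.candidates[0].lam:g}, {self.candidates[-1].lam:g}]")
        add(f"Selected by {self.criterion}: lambda = {w.lam:g}")
        add("-" * 51)
        add(f"Edges (manifest): {w.pattern.KS:>6} of {w.pattern.K_bar}"
            f"   zeros N0: {w.pattern.N0}   Nef: {w.n_ef}")
        if w.scores:
            add("-" * 51)
            add("criterion            value      winner lambda")
            for name in sorted(w.scores):
                v = w.scores[name]
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    continue
                sel = self.candidates[self.selected[name]].lam \
                    if name in self.selected else float("nan")
                add(f"{name:<12} {v:>14.3f} {sel:>14g}")
        names = m.series.names
        edges = w.pattern.edges()
        add("-" * 51)
        add(f"Conditional-dependence edges ({len(edges)}):")
        for a, b in edges[:40]:
            add(f"  {names[a]} -- {names[b]}")
        if len(edges) > 40:
            add(f"  ... ({len(edges) - 40} more)")
        return "\n".join(lines)

    def __repr__(self):
        ok = sum(not c.failed for c in self.candidates)
        return (f"<LatentGraphicalVARResults: {ok}/{len(self.candidates)} "
                f"candidates, criterion={self.criterion}>")

    def plot_criterion(self, names=None, ax=None):
        """Criterion value against the penalty (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = [self.criterion] if names is None else list(names)
        for name in names:
            lams = [c.lam for c in self.candidates if not c.failed]
            vals = [c.scores.get(name, np.nan) for c in self.candidates
                    if not c.failed]
            ax.plot(lams, vals, marker="o", ms=3, label=name)
        ax.set_xlabel("lambda")
        ax.set_ylabel("criterion value")
        ax.legend()
        return ax


class SparseLowRankVARResults:
    """Solution of the sparse-plus-low-rank program for one penalty pair."""

    def __init__(self, model, X, L, pattern, isdm, lam, gamma):
        self.model = model
        self.X = X
        self.L = L
        self.pattern = pattern
        self.isdm = isdm
        self.lam = lam
        self.gamma = gamma

    def lowrank_rank(self, rel_tol: float = 1e-3) -> int:
        """Numerical rank of the low-rank block ``L``."""
        w = np.linalg.eigvalsh(self.L.value)
        return int((w > rel_tol * max(w.max(), 1e-300)).sum())

    def fit_manifest_var(self):
        """Spectrally factorize the sparse ISDM estimate and fit residuals."""
        factor = specfact.spectral_factorize(self.isdm)
        sigma_hat = specfact.residual_covariance(self.model.series,
                                                 factor.ar_coeffs)
        return factor, sigma_hat

    def __repr__(self):
        return (f"<SparseLowRankVARResults lam={self.lam} "
                f"gamma={self.gamma} N0={self.pattern.N0}>")
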