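"""Simulation-study drivers: oracle evaluation, criterion comparison and
the sparse-plus-low-rank baseline sweep.

Each study simulates series from the synthetic latent-variable model
(one model per sparsity level ``KS``, shared across trials), runs an
estimation sweep, and reports the pattern distance — the number of
below-diagonal cells where an estimated pattern differs from the truth —
either minimized over the candidate set (the oracle) or at the candidate
selected by each criterion/score function.

Seeds are derived deterministically from ``(config.seed, KS, trial)`` so
that re-running a study reproduces its tables exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import emloop, selection
from .maxent import SolverError, solve_sparse_lowrank
from .specfact import residual_covariance, spectral_factorize
from .varsim import (TrigMatrixPolynomial, generate_synthetic_model,
                     pattern_distance, sample_covariances, simulate_var)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "desk_preset", "paper_preset",
           "run_oracle_study", "run_selection_study", "run_algosl_study",
           "aggregate_distances"]


@dataclass
class StudyConfig:
    """Settings of the synthetic study."""

    ks_values: tuple = (2, 3, 15)
    n_trials: int = 10
    T: int = 50_000
    K: int = 15
    r: int = 1
    p: int = 1
    scale: float = 1.0
    lambda_grid: np.ndarray = field(
        default_factory=emloop.default_lambda_grid)
    nit_values: tuple = (2,)
    threshold: float = 1e-3
    adaptive: bool = True
    freq_grid: int = 512
    gamma: float = 1.0
    seed: int = 0
    score_penalized: bool = False
    # sparse+low-rank grid (lambda, gamma) pairs are the outer product
    sl_lambdas: tuple = tuple(np.round(np.arange(0.1, 0.61, 0.1), 10))
    sl_gammas: tuple = tuple(np.round(np.arange(0.01, 0.501, 0.01), 10))
    solver_options: dict = field(default_factory=lambda: dict(gap_tol=1e-4))

    def model_for(self, KS: int):
        return generate_synthetic_model(
            KS=KS, K=self.K, r=self.r, p=self.p, scale=self.scale,
            seed=(self.seed, KS))

    def series_for(self, model, KS: int, trial: int):
        return simulate_var(model, self.T,
                            seed=(self.seed, KS, trial)).manifest(self.K)

    def to_manifest(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["lambda_grid"] = [float(v) for v in self.lambda_grid]
        doc["sl_lambdas"] = [float(v) for v in self.sl_lambdas]
        doc["sl_gammas"] = [float(v) for v in self.sl_gammas]
        return doc


def desk_preset(seed: int = 0, **overrides) -> StudyConfig:
    """Scaled-down study preset for quick runs on a single CPU."""
    base = dict(
        n_trials=3,
        lambda_grid=np.round(np.linspace(0.005, 0.1, 20), 10),
        sl_lambdas=tuple(np.round(np.arange(0.1, 0.61, 0.1), 10)),
        sl_gammas=(0.01, 0.05, 0.1, 0.3, 0.5),
        seed=seed,
    )
    base.update(overrides)
    return StudyConfig(**base)


def paper_preset(seed: int = 0, **overrides) -> StudyConfig:
    """Full protocol: 10 trials, 100-point penalty grid, 300 pairs."""
    base = dict(n_trials=10, seed=seed)
    base.update(overrides)
    return StudyConfig(**base)


def _em_config(config: StudyConfig, nit: int, scores: bool):
    return emloop.AlgoEMConfig(
        p=config.p, r=config.r, lambda_grid=config.lambda_grid,
        n_it=nit, threshold=config.threshold, adaptive=config.adaptive,
        freq_grid=config.freq_grid, gamma=config.gamma,
        compute_scores=scores, skip_constrained=not scores,
        score_penalized=config.score_penalized,
        solver_options=dict(config.solver_options))


def run_oracle_study(config: StudyConfig) -> pd.DataFrame:
    """Minimum pattern distance over the penalty grid, per (KS, Nit, trial).

    Only the penalized loop is run: the constrained loop never changes the
    extracted pattern, and the oracle needs patterns only.
    """
    rows = []
    for KS in config.ks_values:
        model, truth, _ = config.model_for(KS)
        for trial in range(config.n_trials):
            series = config.series_for(model, KS, trial)
            for nit in config.nit_values:
                t0 = time.time()
                run = emloop.run_algoem(
                    series, _em_config(config, nit, scores=False),
                    true_pattern=truth)
                d = run.min_distance_to(truth)
                rows.append(dict(KS=KS, Nit=nit, trial=trial, distance=d))
                logger.info("oracle KS=%d Nit=%d trial=%d: distance=%d "
                            "(%.1fs)", KS, nit, trial, d, time.time() - t0)
    return pd.DataFrame(rows)


def run_selection_study(config: StudyConfig) -> pd.DataFrame:
    """Distance of each selector's chosen pattern, per (KS, trial).

    Rows carry the selection stage: ``constrained`` scores the models
    refit under the extracted patterns (the full algorithm), and, when
    ``config.score_penalized`` is set, ``penalized`` scores the
    first-loop estimates directly.
    """
    nit = config.nit_values[0]
    rows = []
    for KS in config.ks_values:
        model, truth, _ = config.model_for(KS)
        for trial in range(config.n_trials):
            series = config.series_for(model, KS, trial)
            t0 = time.time()
            run = emloop.run_algoem(
                series, _em_config(config, nit, scores=True),
                true_pattern=truth)
            for stage, selected in (("constrained", run.selected),
                                    ("penalized", run.selected_penalized)):
                if not selected:
                    continue
                for name, idx in selected.items():
                    d = pattern_distance(run.candidates[idx].pattern, truth)
                    rows.append(dict(KS=KS, trial=trial, stage=stage,
                                     selector=name, distance=d))
            logger.info("selection KS=%d trial=%d done (%.1fs)",
                        KS, trial, time.time() - t0)
    return pd.DataFrame(rows)


def _score_sl_candidate(series, X, pattern, r0_hat, p, T, gamma, r,
                        correlogram_evals, grid_omega):
    # score functions use the solved manifest ISDM directly (no VAR
    # coefficients needed); the IT criteria need Sigma_hat, obtained by
    # factorizing the estimate and fitting residuals
    isdm = TrigMatrixPolynomial(X.isdm_coeffs())
    factor = spectral_factorize(isdm)
    sigma_hat = residual_covariance(series, factor.ar_coeffs)
    entropy_rate = None
    if correlogram_evals is not None:
        try:
            entropy_rate = selection.relative_entropy_rate(
                correlogram_evals, den_inverse=isdm.evaluate(grid_omega))
        except ValueError:
            entropy_rate = None
    return selection.score_all_criteria(
        sigma_hat, r0_hat, pattern, p, T, gamma=gamma,
        entropy_rate=entropy_rate, r=r)


def run_algosl_study(config: StudyConfig) -> pd.DataFrame:
    """Sparse-plus-low-rank sweep over the (lambda, gamma) grid.

    For every pair the convex program is solved on the manifest sample
    covariances, the pattern extracted from the sparse part by the same
    PSC thresholding, and all selectors scored; rows report the distance
    of each selector's pick (plus the oracle).
    """
    from .varsim import omega_grid

    p, r = config.p, config.r
    grid_omega = omega_grid(config.freq_grid)
    rows = []
    for KS in config.ks_values:
        model, truth, _ = config.model_for(KS)
        for trial in range(config.n_trials):
            series = config.series_for(model, KS, trial)
            cov = sample_covariances(series, p)
            _, corr_evals = selection.correlogram_bartlett(
                series, None, config.freq_grid)
            cands = []
            t0 = time.time()
            warm = None
            for lam in config.sl_lambdas:
                for gam in config.sl_gammas:
                    try:
                        X, L = solve_sparse_lowrank(
                            cov, float(lam), float(gam), warm=warm,
                            **config.solver_options)
                        warm = X._z
                        sparse_poly = TrigMatrixPolynomial(
                            [X.D(i) + L.D(i) for i in range(p + 1)])
                        pattern = emloop.extract_pattern(
                            sparse_poly, config.threshold, config.K,
                            config.freq_grid)
                        scores = _score_sl_candidate(
                            series, X, pattern, cov.lag(0), p, series.T,
                            config.gamma, r, corr_evals, grid_omega)
                        cands.append((pattern, scores))
                    except (SolverError, ValueError,
                            np.linalg.LinAlgError) as exc:
                        logger.warning("AlgoSL KS=%d trial=%d (%g, %g) "
                                       "failed: %s", KS, trial, lam, gam,
                                       exc)
            if not cands:
                continue
            dists = [pattern_distance(pat, truth) for pat, _ in cands]
            rows.append(dict(KS=KS, trial=trial, selector="oracle",
                             distance=int(min(dists))))
            names = set().union(*(sc.keys() for _, sc in cands))
            for name in sorted(names):
                vals = [sc.get(name, np.nan) for _, sc in cands]
                vals = [np.inf if v is None or np.isnan(v) else v
                        for v in vals]
                best = int(np.argmin(vals))
                if np.isfinite(vals[best]):
                    rows.append(dict(KS=KS, trial=trial, selector=name,
                                     distance=dists[best]))
            logger.info("AlgoSL KS=%d trial=%d done (%.1fs, %d candidates)",
                        KS, trial, time.time() - t0, len(cands))
    return pd.DataFrame(rows)


def aggregate_distances(df: pd.DataFrame, by=None) -> pd.DataFrame:
    """Trial-averaged distances."""
    if by is None:
        by = [c for c in ("KS", "Nit", "stage", "selector")
              if c in df.columns]
    return (df.groupby(by)["distance"].mean()
            .reset_index().rename(columns={"distance": "avg_distance"}))


def save_study(outdir, name: str, df: pd.DataFrame,
               config: StudyConfig) -> None:
    """Write the per-trial table, the aggregate and a config manifest."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{name}_trials.tsv", sep="\t", index=False)
    aggregate_distances(df).to_csv(out / f"{name}_summary.tsv", sep="\t",
                                   index=False)
    with open(out / f"{name}_config.json", "w") as fh:
        json.dump(config.to_manifest(), fh, indent=1)
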