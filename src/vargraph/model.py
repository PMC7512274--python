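"""Model classes: the user-facing entry points of the package.

`LatentGraphicalVAR` follows the statsmodels convention: construct the
model from data, call :meth:`fit`, and work with the returned results
object.  The fit sweeps the penalty grid of the maximum-entropy EM
algorithm and selects the winning sparsity pattern with an
information-theoretic criterion.

`SparseLowRankVAR` exposes the sparse-plus-low-rank decomposition of the
manifest ISDM (the comparison method) with the same results interface for
a single penalty pair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import emloop, maxent
from .results import LatentGraphicalVARResults, SparseLowRankVARResults
from .varsim import (DEFAULT_FREQ_GRID, SparsityPattern, TimeSeries,
                     TrigMatrixPolynomial, read_timeseries,
                     sample_covariances)

__all__ = ["LatentGraphicalVAR", "SparseLowRankVAR"]


class LatentGraphicalVAR:
    """Latent-variable graphical model of a multivariate time series.

    Parameters
    ----------
    endog : array-like or DataFrame, shape (T, K)
        Observed (manifest) series, one column per variable.
    order : int
        VAR order ``p`` (assumed known).
    n_latent : int
        Number of latent variables ``r`` (assumed known, typically 1).

    Examples
    --------
    >>> model = LatentGraphicalVAR(data, order=1, n_latent=1)
    >>> res = model.fit(criterion="RNMLFD")
    >>> print(res.summary())
    """

    def __init__(self, endog, order: int = 1, n_latent: int = 1, names=None):
        if isinstance(endog, pd.DataFrame):
            names = list(endog.columns) if names is None else names
            endog = endog.to_numpy(dtype=float)
        elif isinstance(endog, TimeSeries):
            names = endog.names if names is None else names
            endog = endog.data
        self.series = TimeSeries(np.asarray(endog, dtype=float), names)
        if order < 0:
            raise ValueError("order must be nonnegative")
        if n_latent < 0:
            raise ValueError("n_latent must be nonnegative")
        self.order = int(order)
        self.n_latent = int(n_latent)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, order: int = 1,
                       n_latent: int = 1) -> "LatentGraphicalVAR":
        return cls(df, order=order, n_latent=n_latent)

    @classmethod
    def from_csv(cls, path, order: int = 1, n_latent: int = 1,
                 sep=None) -> "LatentGraphicalVAR":
        return cls(read_timeseries(path, sep=sep), order=order,
                   n_latent=n_latent)

    @property
    def K(self) -> int:
        return self.series.dim

    def fit(self, lambda_grid=None, n_iter: int = 2,
            threshold: float = 1e-3, adaptive: bool = True,
            criterion: str = "RNMLFD", gamma: float = 1.0,
            freq_grid: int = DEFAULT_FREQ_GRID,
            bartlett_window: int | None = None,
            score_penalized: bool = False,
            skip_constrained: bool = False,
            compute_scores: bool = True,
            solver_options: dict | None = None,
            true_pattern: SparsityPattern | None = None,
            ) -> LatentGraphicalVARResults:
        """Run the EM sweep and select the conditional-independence graph.

        Parameters mirror the algorithm settings: ``lambda_grid`` defaults
        to the regular grid on ``[1e-3, 1e-1]`` with step ``1e-3``;
        ``n_iter`` is the EM iteration count of each loop; ``threshold``
        is the partial-spectral-coherence cut-off; ``adaptive`` carries the
        latent coupling across the grid; ``criterion`` picks the winner.
        """
        if lambda_grid is None:
            lambda_grid = emloop.default_lambda_grid()
        config = emloop.AlgoEMConfig(
            p=self.order, r=self.n_latent,
            lambda_grid=np.asarray(lambda_grid, dtype=float),
            n_it=n_iter, threshold=threshold, adaptive=adaptive,
            freq_grid=freq_grid, criterion=criterion, gamma=gamma,
            bartlett_window=bartlett_window,
            score_penalized=score_penalized,
            skip_constrained=skip_constrained,
            compute_scores=compute_scores,
            solver_options=solver_options or {})
        run = emloop.run_algoem(self.series, config,
                                true_pattern=true_pattern)
        return LatentGraphicalVARResults(self, run)


class SparseLowRankVAR:
    """Sparse-plus-low-rank decomposition of the manifest ISDM.

    One call to :meth:`fit` solves the convex program for a single
    ``(lam, gamma)`` pair; candidate sets over a grid of pairs are built
    by the study drivers in :mod:`vargraph.experiments`.
    """

    def __init__(self, endog, order: int = 1, names=None):
        if isinstance(endog, pd.DataFrame):
            names = list(endog.columns) if names is None else names
            endog = endog.to_numpy(dtype=float)
        elif isinstance(endog, TimeSeries):
            names = endog.names if names is None else names
            endog = endog.data
        self.series = TimeSeries(np.asarray(endog, dtype=float), names)
        self.order = int(order)
        self._cov = None

    @property
    def K(self) -> int:
        return self.series.dim

    def fit(self, lam: float, gamma: float, threshold: float = 1e-3,
            freq_grid: int = DEFAULT_FREQ_GRID,
            solver_options: dict | None = None,
            warm=None) -> SparseLowRankVARResults:
        if self._cov is None:
            self._cov = sample_covariances(self.series, self.order)
        opts = solver_options or {}
        X, L = maxent.solve_sparse_lowrank(self._cov, lam, gamma,
                                           warm=warm, **opts)
        sparse_poly = TrigMatrixPolynomial(
            [X.D(i) + L.D(i) for i in range(self.order + 1)])
        pattern = emloop.extract_pattern(sparse_poly, threshold, self.K,
                                         freq_grid)
        isdm = TrigMatrixPolynomial(X.isdm_coeffs())
        return SparseLowRankVARResults(self, X, L, pattern, isdm,
                                       lam=lam, gamma=gamma)
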