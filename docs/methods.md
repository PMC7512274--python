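# Methods

## Model

`vargraph` estimates the conditional-independence graph of a
multivariate stationary time series under a latent-variable
vector-autoregressive (VAR) model.  The full process has
`kappa = K + r` components — `K` observed ("manifest") variables and
`r` hidden ("latent") ones, with `r << K` — and evolves as

    x_t = A_1 x_{t-1} + ... + A_p x_{t-p} + eps_t,
    eps_t ~ N(0, Sigma),  Sigma > 0,

with all companion eigenvalues strictly inside the unit circle.  The
object of interest is the inverse spectral density matrix (ISDM)

    Phi^{-1}(w) = A(w)^H Sigma^{-1} A(w) = sum_{i=-p}^{p} Q_i e^{-jwi},
    A(w) = -sum_{i=0}^{p} A_i e^{-jwi},  A_0 = -I,

because two manifest components a and b are conditionally independent
given all the others (and the latents) exactly when the (a, b) entry of
Phi^{-1}(w) vanishes at every frequency.  The sparsity pattern of the
manifest block of the ISDM is therefore the adjacency matrix of the
conditional-independence graph.

Only manifest covariances can be estimated from data.  Marginalizing the
latent variables turns the manifest ISDM into a sparse-minus-low-rank
object, `Phi_m^{-1} = S - Lambda`: hidden confounders add a low-rank
distortion that would destroy the sparsity if ignored.  The estimator
works with the full-model ISDM, normalized so that the latent block is
the identity (unit latent variances, latents conditionally independent
given the manifest variables); the latent effect is carried entirely by
the latent-manifest coupling polynomial `Ups_lm(w)`.

## Estimation: maximum-entropy EM

Missing latent covariances are handled by an EM scheme whose
maximization step is a convex log-det semidefinite program over a
block-parameter matrix `X` of size `kappa(p+1)`, linked to the ISDM
coefficients through the block-trace operator `D_i(X)` (the sum of the
blocks on the i-th block super-diagonal).

* **Initialization.** The classical maximum-entropy problem on the
  manifest sample covariances,
  `min tr(T(R_hat) X) - logdet X_00` over PSD `X` (equivalent to the
  Yule–Walker fit), gives the manifest ISDM; the latent coupling is
  initialized from the leading eigenpair(s) of the lag-zero coefficient,
  `G = D^{1/2}(1:r,1:r) U(:,1:r)^T`.

* **Expectation step.** Given the current coupling, the full covariance
  lags are completed in closed form.  The manifest block is the sample
  covariance `R_hat_i`; the latent-manifest block is the (negated)
  polynomial convolution `C_lm = -Ups_lm(w) Phi_hat_m(w)` computed to
  degree `2p`; the latent block is `C_l(w) = I + Ups_lm Phi_hat_m
  Ups_lm^T(-w)`, i.e. `C_{l,i} = delta_i I - sum_k C_{lm,k}
  Q_{lm,k-i}^T`, truncated back to degree `p`.  Writing the quadratic
  term with this sign and index orientation keeps `C_l(w) >= I`, as the
  frequency-domain identity requires; the truncation to degree `p` is
  the model-class projection, not an approximation choice.  (Since the
  maximization below fixes the latent block of `D_i(X)` by constraint,
  the latent completion block only shifts the objective by a constant;
  it is still computed correctly for diagnostics and validity of the
  Toeplitz embedding.)

* **Maximization step (penalized loop).** With completed covariances
  `C`, solve

      min_X tr(T(C) X) - logdet X_00 + lambda f(X)
      s.t.  X >= 0,
            D_0(X) latent block = I,  D_i(X) latent block = 0 (i >= 1),

  where `f` is a group-sparsity promoter over manifest pairs: for each
  below-diagonal pair (a, b) it adds the max of the absolute values of
  all the independent coefficients of the (a, b) ISDM polynomial —
  `D_0(X)(a,b)` together with `D_i(X)(a,b)` **and** `D_i(X)(b,a)` for
  `i = 1..p`.  Including the (b, a) cells for `i >= 1` is essential:
  they are the coefficients `Q_{-i}(a,b)` of the same off-diagonal
  polynomial, and leaving them unpenalized lets the optimizer move all
  conditional dependence into them, making the penalty vacuous.  The
  same convention (both cells, all lags) is used by the hard-zero
  constraints of the pattern-constrained program below, and the
  `sparsity_promoter` function reports the same extended max.

  `Nit` alternations of expectation and maximization are run per
  penalty value (default `Nit = 2`).  In the *adaptive* variant the
  coupling estimate is carried from each penalty value to the next
  (the grid step is small), instead of re-initializing from the
  eigen-decomposition; this markedly stabilizes the sweep and is the
  default.

* **Pattern extraction.** The penalized estimate is reduced to a
  pattern by partial spectral coherence (PSC): for each manifest pair,

      max_w |Phi^{-1}(w)_ab| / sqrt(Phi^{-1}(w)_aa Phi^{-1}(w)_bb)

  over a uniform frequency grid (512 points on (-pi, pi] by default);
  the edge is absent when the maximum does not exceed the threshold
  `Th` (default 1e-3).  The normalized, modulus form is used (the ratio
  is scale-invariant and lies in [0, 1]).

* **Constrained loop.** The pattern is then enforced exactly: the same
  EM alternation with the penalty replaced by hard zeros on the excluded
  cells (`D_i(X)(a,b) = D_i(X)(b,a) = 0` for all `i` whenever the
  pattern excludes (a, b)).  This is a maximum-entropy covariance
  extension: when the truth satisfies the pattern and the latent
  normalization, exact covariances are completed to the exact ISDM.

* **Model scoring.** The final ISDM polynomial, positive definite on
  the grid, is spectrally factorized into a stable VAR model; the
  coefficients are truncated to their manifest blocks, one-step-ahead
  residuals on the data give `Sigma_hat` (divisor `T - p`), and the
  selection criteria below are evaluated.  The candidate minimizing the
  configured criterion wins.

## Model selection

With `N0` the below-diagonal zero count of a pattern and
`K_bar = K(K-1)/2`, the effective parameter count is
`Nef = K(K+1)/2 - N0 + p(K^2 - 2 N0)` and `eta = Nef/K`.  The criteria
(all "smaller is better", `ld = logdet Sigma_hat`):

    SBC    = T ld + Nef log T
    AICc   = T ld + 2 Nef T / (T - Nef - 1)
    logFPE = ld + K log((T + eta)/(T - eta))
    RNML   = (T - eta - K + 1)/2 ld + Nef/2 log tr(R_hat_0 - Sigma_hat)
             - log Gamma_K((T - eta)/2) - log Gamma(Nef/2)
    EBIC   = SBC + 2 gamma log C(K_bar, N0)
    EBICFD = SBC + 4 gamma Nef log K
    RNMLFD = RNML + 2 Nef log K

`gamma` defaults to 1.  The extended criteria add a code length for the
size of the model family; the fully-dimensional variants (EBICFD,
RNMLFD) penalize proportionally to `Nef log K`, which — unlike the
binomial term of EBIC, maximal at `N0 = K_bar/2` — decreases
monotonically with sparsity.

Score functions use the relative entropy rate between the
Bartlett-windowed correlogram `Phi_c` and the fitted manifest spectrum
`Phi_m`,

    D(Phi_c || Phi_m) = -(1/4pi) Int [logdet Om + tr(I - Om)] dw,
    Om(w) = Phi_c(w) Phi_m^{-1}(w),

with `Ne = K(K-1)/2 - N0 + rK` edges (for `r = 1` this is
`K(K+1)/2 - N0`):

    log SF1 = log D + log Ne,   SF2 = D + Ne/T,   SF3 = D + Ne log T / T.

The Bartlett window length defaults to `floor(sqrt(T))` (standard
correlogram practice; the value is configurable because the score
functions depend on it).  The integral is a trapezoid rule on the same
512-point grid — the integrand is smooth and periodic, so this is
spectrally accurate.  The generalization of `Ne` to `r >= 2` assumes
each latent couples to every manifest variable; it is a convention of
this package.

## Convex solver

The maximization steps and the sparse-plus-low-rank baseline

    min_{X,L>=0} tr(T(R_hat) X) - logdet X_00
                 + lambda gamma f(X + L) + lambda tr(L)

are log-det semidefinite programs with linear equalities and an
L1-of-Linf penalty.  They are solved by a purpose-built feasible-start
barrier (path-following Newton) method in `vargraph._solver`:

* variables are the scaled lower-triangle vectorizations of the PSD
  blocks plus one epigraph slack per penalized pair;
* the central-path subproblems `t f_0(z) + phi(z)` are minimized by
  equality-constrained Newton steps (dense KKT systems; all problems
  here have a few hundred to ~1000 variables);
* the log-det Hessians are assembled by vectorized indexing of the
  block inverses; backtracking line search maintains strict
  feasibility (Cholesky tests for the cones, analytic step caps for the
  linear slacks);
* the barrier parameter is increased by a factor 10 per stage with
  loose intermediate centering, and the reported `gap` is the standard
  bound `nu/t` on the suboptimality.

Convexity makes the solutions solver-independent up to tolerance; the
unpenalized problem is verified against the closed-form Yule–Walker fit
to 1e-4 and tighter.  The default gap tolerance is 1e-6; the study
drivers use 1e-4, which leaves ISDM coefficient errors around 1e-5 —
two orders of magnitude below the PSC threshold.  Warm starts are used
along the penalty grid and across EM iterations; they change solve
times, not solutions.

## Spectral factorization

A positive ISDM polynomial is factorized as
`Phi^{-1} = A(w)^H Sigma^{-1} A(w)` with `A_0 = -I`, `Sigma > 0` and a
stable (minimum-phase) factor, which is unique under this
normalization.  The implementation treats the transposed coefficients
as the covariance lags of a moving-average process and iterates the
associated discrete Riccati fixed point

    P <- A P A^T + (G - A P C^T)(Q_0^T - C P C^T)^{-1}(G - A P C^T)^T

from `P = 0` (monotone convergence to the stabilizing solution for any
spectrum positive on the circle; tolerance 1e-14 on the iterates).  The
innovation representation then yields the factor.  Stability of the
recovered model is asserted on every factorization; round-trips through
construction and factorization agree to better than 1e-10 on the study
models.  An SDP-based factorization would give the same factor by
uniqueness; the Riccati iteration is preferred for speed and has no
tuning parameters.

## Synthetic data generator

`generate_synthetic_model` builds the study truth: full `(K+r)`-ISDM
coefficients `Q_0..Q_p` with unit diagonals; `KS` below-diagonal
manifest cells (and their mirror images) set to `scale * 0.5/(i+1)`;
latent couplings on the last `r` rows/columns set to
`scale * 0.3/(i+1)`; integer multiples of the identity added to `Q_0`
until the polynomial is positive definite on a dense grid (512 points,
tolerance 1e-8); spectral factorization to a stable VAR model that is
then simulated (Gaussian innovations, zero initial state, 1000-sample
burn-in).  Defaults: `K = 15`, `r = 1`, `p = 1`, `T = 50,000`;
`scale = 50` reproduces the strong-signal short-series variant
(`T = 500`).  The exact positions of the `KS` nonzero cells are drawn
deterministically from the seed (they are not identifiability-relevant;
the studies depend on the density, not the cell coordinates), and can
be passed explicitly.

Two deliberate properties of this truth: the latent block of the
constructed ISDM is *not* `(I, 0)` (the identity additions and the unit
diagonal of `Q_1` land there too), so the generator's models lie
slightly outside the estimator's normalized class — as real confounders
would; and the manifest zero cells are exact zeros in every
coefficient.  Tests that require an in-class truth (exact
maximum-entropy recovery) therefore build a separate latent-normalized
model; tests of the full pipeline use the generator.

What the generator does not emulate: non-Gaussian innovations, trends
or nonstationarity, measurement noise, missing data, and
frequency-dependent latent variance profiles beyond what the VAR class
produces.  Passing the synthetic studies shows the estimator recovers
the graph under the stated model; it does not certify behavior under
those violations.

## Study protocols and problem sizes

The evaluation metric is the pattern distance: the number of
below-diagonal cells where an estimated pattern differs from the truth
(range `0..K_bar`; 105 for `K = 15`).  The oracle selects, from an
algorithm's candidate set, the pattern closest to the truth — a lower
bound for every selection rule on the same candidates.

The full protocol (the `paper` preset) uses `Ntr = 10` trials of
`T = 50,000`, a 100-point penalty grid on `[1e-3, 1e-1]`, `Th = 1e-3`,
and for the sparse-plus-low-rank baseline the 300 pairs
`lambda in {0.1..0.6} x gamma in {0.01..0.5}`.  The `desk` preset and
the acceptance checks scale this down to keep single-CPU runs short:
3 trials (1 per setting for the `Nit`-matrix and criterion studies), a
20-point grid on `[0.005, 0.1]` (12 points in the acceptance checks),
and a 30-pair baseline grid with 2 trials.  `T` is kept at 50,000 —
the statistical regime matters more than the grid resolution, and the
recovered-pattern plateau spans a wide `lambda` range, so the thinner
grids still intersect it.  All seeds derive deterministically from
`(seed, KS, trial)`.

## Known limitations

* `p` and `r` are assumed known; no order selection is provided (the
  effective-parameter count would need modification for selecting `r`).
* The barrier solver is dense; it is sized for `K` up to a few tens,
  not hundreds.
* The EM objective is nonconvex across loops; the adaptive sweep is a
  heuristic that works well empirically but carries no global
  guarantee.
* ISDM entries shrunk by the penalty are small, not exactly zero; the
  PSC threshold is what declares absence.  Results can be sensitive to
  `Th` for data far from the study conditions.
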