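# Methods

## The hull diagnostic

For ordinary linear regression, membership of a prediction point in the
independent variable hull (IVH) is decided by scaled prediction variance:
`x0'(X'X)^-1 x0 <= max diag(X(X'X)^-1 X')`. The generalized hull (gIVH)
keeps the variance comparison and drops the linear-model specifics: a
prediction location is an interpolation when the response-scale variance
of its *mean* prediction does not exceed the maximum such variance over
the sampled locations. Two properties follow directly and are enforced
as invariants: sampled locations are always inside their own hull (ties
count as inside — the defining inequality is non-strict, resolved
numerically with a 1e-10 relative tolerance), and the flags are invariant
to any common positive rescaling of the variances, which is why the
linear-Gaussian special case reduces exactly to Cook's leverage rule
regardless of the error variance.

Three variance routes are implemented and agree in the small-variance
limit (tested):

* **delta** — first-order propagation through the inverse link,
  `var(lambda) = D var(mu) D` with `D = d g^-1(mu)/d mu` diagonal for
  univariate links. The response-scale map is taken to be the *inverse*
  link throughout (mean = g^-1(mu)); the variance is exact only to first
  order, underestimating the lognormal variance by ~1.5% at
  var(mu) = 0.01 and more for larger variances.
* **posterior** — the sample variance of the mean response across
  posterior coefficient draws; the default for the Bayesian models.
* **bootstrap** — draws from Normal(coef, cov) pushed through the
  design and inverse link; the frequentist fallback for the GAM.

In every route the iid lognormal observation noise is **excluded** from
the hull variance: the hull measures uncertainty in the mean prediction,
not in a future observation. Only variance diagonals are ever formed;
full prediction covariance is never materialized.

## Observation model and estimators

Counts follow a log-Gaussian Cox observation model:
`Y_i ~ Poisson(lambda_i)`, `log lambda_i = log P_i + log A_i + x_i'b + eps_i`,
with `P_i` the surveyed fraction of cell *i* (the quadrat), `A_i` the
habitat fraction, and `eps_i ~ N(0, s2)` iid overdispersion. Abundance
predictions use `N_i ~ Poisson(A_i lambda_i)` at `P = 1`, where
`lambda_i` includes a fresh `eps_i` draw per posterior draw — the noise
is part of the intensity, and omitting it would shrink every prediction
by the lognormal factor `exp(s2/2)`.

**Bayesian GLM.** Priors: coefficients `N(0, 10^2)` independently,
`s2 ~ InvGamma(0.1, 0.1)`. The sampler is Metropolis-within-Gibbs on a
latent parameterization: per-site random-walk Metropolis on the latent
linear predictors `eta_i = x_i'b + eps_i` (vectorized; proposal scales
adapted every 50 iterations of burn-in toward 0.3 acceptance, then
frozen), followed by the exact Gaussian conditional for the coefficients
and the conjugate inverse-gamma draw for `s2`. Latent-Gaussian
conditioning makes the coefficient update exact, so mixing is governed
only by the univariate eta updates.

**STRM (restricted spatial regression).** The fixed-effect design over
the full prediction grid is augmented with spatial random effects in the
reduced-rank Moran basis: with adjacency `A` (rook), fixed design `X`
(full grid, n rows), `Pperp = I - X(X'X)^-1 X'` and `c = n / (1'A1)`,
the basis `K` collects eigenvectors of `c * Pperp A Pperp` with
eigenvalue above 0.5 (the scaled form of the operator; the threshold is
applied to `c`-scaled eigenvalues). The prior precision of the spatial
coefficients is the ICAR form projected to the basis,
`K'(diag(A1) - A)K`, scaled by a variance with an `InvGamma(0.1, 0.1)`
hyperprior. By construction `K'X = 0`, so the random effects cannot
alias the fixed effects, and the same Gibbs sampler applies to the
augmented coefficient vector. An eigen-threshold above the spectrum
degenerates (with a warning) to the GLM — used as an exactness check.

**Quasi-Poisson GAM.** One penalized spline per covariate:
B-spline bases of `basis_size` functions (cubic for sizes >= 4; a basis
of exactly 3 is a single-segment quadratic, the smallest smooth basis)
with second-order difference penalties and sum-to-zero constraints
absorbed by null-space reparameterization. Fitting is penalized IRLS; a
single shared smoothing parameter minimizes deviance-based GCV
`n D / (n - edf)^2` over a log-spaced grid (deviance was preferred to the
Pearson statistic after the latter proved prone to oversmoothing at low
counts); dispersion is Pearson chi-square over residual degrees of
freedom, and the coefficient covariance is the Bayesian posterior
covariance `phi (X'WX + S)^-1` of the penalized fit. A covariate that is
constant over the fitted cells contributes no smooth and is reported in
`degenerate_smooths_`.

## The synthetic landscape

The generator emulates the structure of a gridded aerial-survey count
study: covariates are zero-mean unit-variance Gaussian fields with
exponential correlation `exp(-d/range)` between cell centers (exact
Cholesky factorization of the 900x900 correlation matrix, cached per
grid/range); expected abundance is log-linear in all covariates with
default coefficients `(log 20, 0.75, -0.75, 0.5)` and range 10 cells on
a 30x30 grid, giving total abundance of order 2-4 x 10^4 with strong
patchiness; realized abundance is one Poisson draw per cell, homogeneous
within cells. Surveys cover `n = 45` cells: the spatially balanced
design orders cells by a randomized recursive-quadrant address and
selects systematically (exactly uniform inclusion probability n/N, the
same balance-plus-randomness trade-off as GRTS); the convenience design
samples without replacement with weights `exp(-d/decay)` from the grid
center, `decay` defaulting to one sixth of the grid side. Counts are
binomial thinnings `Binomial(N_i, coverage * detection)` with
coverage 0.1 and detection 1 by default — abundance is realized first,
so thinning (not an independent Poisson) is the correct observation
process. Presumed-absence augmentation appends certain zeros with
`P = 1` for unsampled cells whose habitat covariate (e.g. ice
concentration on [0,1]) falls below a threshold (0.001 for the
"under 0.1%" rule).

What the generator does **not** emulate: continuous-space point
processes and within-cell heterogeneity, animal movement, imperfect or
heterogeneous detection, species misidentification, temporal dynamics,
and real covariate geometry (coastlines, gradients with trends). Passing
tests therefore demonstrate the extrapolation/bias phenomenology and the
internal consistency of the estimators on stationary Gaussian-field
landscapes, not performance on any particular real survey.

## The simulation experiment

Each replicate: three covariate fields, one abundance surface, one
survey per requested design, one fit per requested model — estimation
models receive only covariates 1 and 2 (a fixed, deliberate
misspecification), with quadratic and first-order interaction fixed
effects for GLM/STRM and per-covariate smooths for the GAM. Bias is the
proportional error `(estimate - truth)/truth` of the posterior median of
total abundance (parametric-bootstrap median for the GAM), computed for
the whole grid and for the cells inside each model's gIVH; restricted
comparisons are subset-matched (estimated total over in-hull cells
against true total over the same cells), the only internally consistent
reading when the hull differs between models. Summaries report mean,
median, quartiles, and the count of errors exceeding 2.0 per
design x model x restriction.

Replicate seeds are derived from the master seed by counter
(`SeedSequence((master, replicate, stream))`), so results are
independent of execution order and any replicate subset is reproducible
in isolation. A failed fit is recorded as missing cells for that
design x model and never aborts the replicate; summaries carry effective
replicate counts.

Problem sizes used by the packaged experiment runner and the
reproduction script: 25 replicates with 5,000-iteration / 1,000-burn-in
chains (configurable up to the published 60,000/10,000 via
`MCMCConfig`). At these sizes the experiment's bulk behavior is stable —
right-skewed unrestricted error with median near zero and materially
positive mean under convenience sampling, near-zero restricted error —
but the *mean* unrestricted error is a heavy-tailed statistic: rare
replicates suffer catastrophic extrapolation explosions (proportional
errors in the tens) that dominate any 25-replicate average. The
restricted-inference comparison, which is the quantity of scientific
interest, is insensitive to these tail events because the hull excludes
precisely the exploding cells.

## Known limitations

* The per-site Metropolis updates mix slowly for cells with very large
  counts; chain lengths below ~1,000 iterations are not recommended.
* Delta-method hull variance understates response-scale variance for
  large `var(mu)`; the posterior route is preferred whenever draws exist.
* The GAM's single shared smoothing parameter trades per-term
  adaptivity for robustness at small n; per-term selection is a
  straightforward extension.
* The spatially balanced design is an accepted approximation to GRTS
  (uniform inclusion, quadrant-structured spreading), not the cited
  algorithm itself; its realized balance is slightly weaker near
  non-power-of-two grid splits.
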