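# Methods

This note describes the statistical machinery implemented in `incproj`:
the model ladder, the inference engine behind the Bayesian models, the
benchmarking design, the synthetic-registry generator, and the numerical
choices that a user of the results should know about.

## Data model

A registry table pairs an incidence-count matrix `Y` and a person-years
matrix `N` on a common grid of calendar years (rows, ascending, step 1)
and age groups (columns, constant width of 1 or 5 years). The default
age filter keeps groups fully contained in [20, 84]: childhood cancers
are biologically distinct and rare, and open-ended top groups ("85+")
break the constant-width Lexis geometry the cohort model needs. Cohort
membership of cell `(i, j)` (1-based age group `i` of `I`, period `j`
of `J`) is `k = j + M(I - i)`, where the grid factor `M` is the
age-group width divided by the period width; there are
`K = M(I - 1) + J` cohorts.

## The model ladder

All models act on rates through a fixed `log N` offset; projections are
reported on the count scale.

1. **Constant projection** — the last observed year's rates (scaled by
   future person-years) or counts, carried forward. Degenerate
   predictive distribution (SD 0); the baseline every other model must
   beat.
2. **Negative-binomial GLMs** — intercept-only, and
   `age + period + age:period` with covariates as numeric midpoints
   centred at their training means (centring keeps the interaction fit
   well-conditioned). Maximum likelihood via `statsmodels` (NB2
   dispersion estimated by ML; a Poisson fallback catches the
   boundary case where the dispersion collapses), or the Bayes engine
   below with a vague Gaussian prior on the coefficients.
3. **Age-smooth GAM** — a B-spline basis in age (replacing the
   intercept) plus a linear period term, same NB family and engines.
   Knots sit at quantiles of the age midpoints with clamped boundaries.
   Default basis sizes are `min(10, ceil(I/2) + 2)` for age and
   `min(8, ceil(J/2) + 2)` for period — mgcv-flavoured defaults that
   keep the basis well below the number of distinct covariate values at
   registry-typical grid sizes; both are constructor arguments.
4. **Bayesian tensor-product smoother (z-model)** — a smooth
   age x period surface written as a classical random-effects term
   `eta = mu + Z z`, where `Z` is the row-wise Kronecker product of
   M-spline marginal bases (M-splines: non-negative B-splines rescaled
   so each basis function integrates to one) and `z ~ N(0, tau^-1 I)`
   with `tau ~ Gamma(1, 0.005)`. The period basis spans the training
   years plus `max_horizon` future years, so projection evaluates the
   same surface; coefficients without data support are informed only by
   the prior, so far extrapolations shrink toward the intercept with
   rapidly widening uncertainty. That widening is a property of the
   iid coefficient prior, not a bug: the z-model has no trend-carrying
   penalty null space.
5. **Bayesian age-period-cohort model** — Poisson likelihood and
   `eta_ij = mu + alpha_i + beta_j + gamma_k + eps_ij` with independent
   second-order random-walk (rw2) priors on the age, period and cohort
   effect vectors and an iid overdispersion effect `eps`. rw2 penalises
   second differences; its null space (constants and linear trends)
   means effects shrink toward local linear trends and extrapolate them
   with growing variance — the behaviour that drives the model's wide,
   honest long-horizon bands.

### Identification in the APC model

Age, period and cohort indices are exactly linearly dependent, so the
three effect vectors are not separately estimable. We impose
sum-to-zero constraints on all three and additionally remove the
cohort effect's linear component. The extra constraint eliminates the
one remaining likelihood-null direction (a linear trend can be moved
between `alpha`, `beta` and `gamma` without changing `eta`), which
would otherwise make the posterior improper and the curvature matrix
singular. Only `eta` and predictive counts are reported as estimands;
both are invariant to this choice (verified by direct construction in
the tests).

### Hyperpriors

Every effect precision (rw2 blocks, iid overdispersion, tensor
coefficients) carries a `Gamma(a = 1, b = 0.005)` prior — proper but
weak, with prior mean precision 200. The NB dispersion in Bayesian
GLM/GAM/tensor fits is parametrised by the size `s` (variance
`mu + mu^2/s`) with a `Gamma(1, 0.01)` prior on `s`. All are
constructor arguments.

## The inference engine

The Bayesian models share one latent Gaussian structure: counts with a
log link and offset, Gaussian fixed effects, and structured random
effects with Gamma-prior precisions. Two inference routes sit behind
one interface; the contract is posterior accuracy, not the algorithm.

**Laplace route (default).** Constraints are removed exactly by
reparametrising each block onto an orthonormal basis of the constraint
null space, so draws satisfy them to machine precision. For fixed
log-precisions `theta`, the conditional posterior of the latent field
is approximated by a Gaussian at the conditional mode (damped Newton
iterations) with the negative Hessian as precision; the mode is then
shifted by the standard third-derivative skewness correction
`0.5 H^-1 U'(l''' * Var[eta])`, which moves the Gaussian centre from
the conditional mode to (first order) the conditional mean. The
hyperparameter posterior is explored by Nelder-Mead on the Laplace
marginal `p(theta | y)`; a Gaussian on the log-precision scale
(finite-difference Hessian, precision floored at 0.25 to guard against
flat objectives) serves as proposal for a set of antithetic `theta`
points which are then importance-reweighted by the true Laplace
marginal. Posterior summaries of `eta` are the analytic moments of the
resulting Gaussian mixture; stored draws are allocated to `theta`
points proportionally to the weights. Generalised log-determinants of
the intrinsic priors use the true ranks (eigendecomposition per block,
computed once). Starting values for the log-precisions are data-scaled:
`tau_0 = mean(||Z_row||^2) / var(log empirical rate)`, which places the
search in the basin where smooth terms are active; starting at the
prior-mean precision instead can converge to a collapsed mode in which
the smooth is flat and fitted dispersion absorbs the signal.

**MCMC route (gold standard).** A one-block sampler: conjugate
Gamma updates for the precisions given the effects; a random-walk
Metropolis step for the NB size; and a joint Metropolis-Hastings update
of the whole latent field using the Gaussian Taylor expansion of the
target at the current state as proposal (acceptance rates ~0.7-0.9 on
the tested problems). It is asymptotically exact and serves as the
independent reference: the test suite requires the Laplace route to
match its `eta` means and SDs within 0.05 posterior-SD units on an
age-period-cohort fixture, and simulation-based calibration on a
miniature rw2 problem to pass a rank-uniformity test.

Likelihood evaluations clip `|eta| <= 40`; Newton weights are floored
at 1e-10 and a 1e-8 ridge is added if a Cholesky factorisation fails.
These guards only bind far outside the posterior bulk.

## Projection

Bayesian projections draw jointly from the stored posterior: rw2
effects (period, cohort) are continued forward by sampling their
predictive — each step doubles back on the local linear trend plus an
innovation with the draw's own precision — and fresh overdispersion
effects are drawn per future cell. ML projections plug the MLE into
the NB/Poisson predictive (no parameter uncertainty; recorded as such).

Two band conventions are computed from the same draws:

- **predictive** — equal-tailed 95% interval of the count-scale
  posterior predictive, observation noise included; integer bounds are
  the smallest values at which the predictive CDF reaches 0.025 and
  0.975. This is the convention under which a correctly specified
  model's bands cover ~95% of future observations, and it is what the
  calibration study checks.
- **expected** — equal-tailed credible interval of the expected count
  `N exp(eta)`. This is the convention the benchmark scores: a model
  earns band width only through genuine uncertainty about the rate
  surface (for the cohort model `eta` includes the overdispersion
  effect), not through fitted dispersion. Under the predictive
  convention an intercept-only NB model is marginally self-calibrating
  — its estimated dispersion absorbs the age structure, the lower
  bound sits at 0 and coverage can mathematically never fall far below
  one half — which would make the benchmark unable to distinguish a
  model that understands the rate surface from one that merely
  inflates its noise term. Published registry benchmarks that report
  intercept-only coverages near zero are implicitly using the
  expected-count convention, and `evaluate()` follows it by default.

## Benchmark design and metrics

For target year `T` (the table's last year), observation length `L`
(default 15) and horizon `n` in {2, 5, 10, 15, 20}: train on
`[T - n - L + 1, T - n]`, predict year `T` using the observed future
person-years (the benchmark isolates rate modelling from demographic
forecasting). Per age cell: coverage indicator (inclusive bounds; a
degenerate constant-model band covers only an exact hit), bias
`100 (obs - pred)/obs` (0 on equality, negative = overestimation;
cells with `obs = 0 != pred` are undefined, excluded, and counted),
and the predictive SD. Cells are aggregated by arithmetic mean into
one record per model x horizon; precision is reported raw and as
`log10(1 + sd)`. The -200 truncation some displays apply to bias is a
plotting convention only; stored records are never truncated. PIT
histograms use the nonrandomised count-data transform
`(F(y) + F(y-1))/2` from predictive samples.

## Synthetic registries

The generator emulates registry extracts: 13 five-year age groups
(20-84), 35 annual periods, log rates decomposing into a parametric age
curve (default log-quadratic spanning roughly 1e-5 to 2e-3 cases per
person-year), a log-linear period drift, an optional age x period
interaction, and a smooth cohort curve built as doubly integrated noise
indexed by `k = j + M(I - i)` so the generative geometry matches the
cohort model exactly. Populations are ~1e5-2e5 person-years per group
with mild age decline and growth. Scenario library: `flat`, `age-only`,
`age+drift`, `age-period-interaction`, `full-apc`, `overdispersed` —
each non-constant model in the ladder is (approximately) correctly
specified for one of them. What the generator does **not** emulate:
registration delay and completeness artefacts, coding changes,
population-forecast error, and abrupt secular breaks (screening
introductions); passing tests therefore demonstrate correctness of the
machinery under the stated generative assumptions, not performance on
any particular real registry.

A second generator draws directly from the cohort model's own process
(rw2 effects with fixed precisions, iid overdispersion, Poisson
counts) for self-consistency and band-calibration studies; its default
precisions (10 for age, 100 for period and cohort, 400 for
overdispersion) produce registry-plausible effect magnitudes (age
curves spanning ~1 log unit, period/cohort wiggles of a few percent
per step).

## Problem sizes used by the shipped studies

The calibration study fits the cohort model to 100 registries of 5 age
groups x 10 training years and scores 2-year-ahead predictive bands
(1000 held-out cells); the engine-agreement fixture is 5 x 8; SBC uses
200 replicates of an 8-cell rw2 problem with 199-draw ranks. These
sizes give the studies enough resolution to detect miscalibration of a
few percent while keeping a full run of the suite and the acceptance
script in the minutes range on a single core.

## Known limitations

- The Laplace route's hyperparameter search is a local optimiser on a
  possibly multimodal marginal; the data-scaled start makes the
  collapsed mode unlikely but not impossible on pathological inputs.
  The `mcmc` route is available for cross-checks.
- Dense linear algebra throughout: fits on single-age SEER-scale grids
  (65 ages x 15 years with per-cell overdispersion effects) involve
  ~1100-dimensional latent fields and take minutes rather than
  seconds; the `maxfev` budget argument trades hyperparameter accuracy
  for time.
- ML projection intervals carry no parameter uncertainty by design.
- Mixed age-group widths in one table are rejected rather than
  harmonised.
- Future person-years must be supplied; no demographic projection is
  included.
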