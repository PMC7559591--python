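"""The projection-model ladder, from constant rates to Bayesian APC.

Every model is an estimator in the scikit-learn idiom: construct with
hyperparameters, ``fit`` on a :class:`~incproj.registry.RegistryTable`,
then ``project`` future counts given future person-years.  All models
act on rates through a ``log N`` offset and return a
:class:`ProjectionResult` holding per-cell predictive means, standard
deviations and equal-tailed 95% intervals on the count scale.

The ladder, in order of complexity:

==========================  ==================================================
:class:`ConstantProjector`   last observed rates (or counts) carried forward
:class:`GLMProjector`        negative-binomial GLM; intercept-only or
                             ``age * period`` with interaction
:class:`AgeSplineGAMProjector`  B-spline smooth in age plus linear period
:class:`TensorSmootherProjector`  Bayesian tensor-product (age x period)
                             smooth via a random-effects z-model with
                             M-spline marginal bases
:class:`BAPCProjector`       Bayesian age-period-cohort model: Poisson
                             likelihood, rw2 age/period/cohort effects,
                             iid overdispersion
==========================  ==================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from . import basis as bas
from . import engine as eng
from .registry import LexisSpec, RegistryTable, cohort_index

__all__ = [
    "ProjectionResult",
    "ConstantProjector",
    "GLMProjector",
    "AgeSplineGAMProjector",
    "TensorSmootherProjector",
    "BAPCProjector",
    "make_projector",
    "MODEL_REGISTRY",
    "project_constant",
    "fit_glm",
    "fit_gam_age_spline",
    "fit_tensor_z",
    "fit_bapc",
    "project",
]


# ---------------------------------------------------------------------
# projection container
# ---------------------------------------------------------------------


@dataclass
class ProjectionResult:
    """Predictive summaries for future cells (rows = years, cols = ages).

    Two band conventions exist, recorded in ``band``:

    ``"predictive"``
        equal-tailed 95% bounds of the count-scale posterior predictive
        (observation noise included): the smallest integers at which
        the predictive CDF reaches 0.025 and 0.975;
    ``"expected"``
        equal-tailed credible bounds of the projected expected count
        ``N * exp(eta)`` — the convention registry benchmarks score,
        where a model earns width only through genuine uncertainty
        about the rate surface, not through fitted dispersion.

    ``samples`` (optional) always holds count-scale predictive draws
    (shape ``(S, n_years, n_ages)``) so PIT histograms are available
    regardless of the band convention.
    """

    years: np.ndarray
    age_lower: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    samples: np.ndarray | None = None
    model: str = ""
    band: str = "predictive"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, yr in enumerate(self.years):
            for c, age in enumerate(self.age_lower):
                rows.append(
                    dict(year=int(yr), age=int(age), mean=self.mean[r, c],
                         sd=self.sd[r, c], lo=self.lo[r, c], hi=self.hi[r, c])
                )
        return pd.DataFrame(rows)

    def last_year(self) -> "ProjectionResult":
        """Summaries for the final projected year only."""
        sel = slice(-1, None)
        return ProjectionResult(
            self.years[sel], self.age_lower, self.mean[sel], self.sd[sel],
            self.lo[sel], self.hi[sel],
            None if self.samples is None else self.samples[:, -1:, :],
            self.model, self.band,
        )

    def predictive_cdf(self, y: np.ndarray) -> np.ndarray:
        """P(Y <= y) per cell, from stored samples."""
        if self.samples is None:
            raise ValueError("projection stored no samples")
        y = np.asarray(y, dtype=float)
        return (self.samples <= y[None, ...]).mean(axis=0)


def _interval_from_samples(draws: np.ndarray, discrete: bool = True):
    """Equal-tailed 95% bounds.  For count draws: smallest integer at
    which the empirical CDF reaches each tail probability; for
    continuous expected-count draws: plain quantiles."""
    method = "inverted_cdf" if discrete else "linear"
    lo = np.quantile(draws, 0.025, axis=0, method=method)
    hi = np.quantile(draws, 0.975, axis=0, method=method)
    return lo, hi


def _summaries(lam_draws: np.ndarray, count_draws: np.ndarray | None,
               years, ages, model: str, band: str,
               keep_samples: bool) -> ProjectionResult:
    """Build a ProjectionResult from expected-count and count draws.

    The predictive mean is always the mean of the expected-count draws
    (same expectation as the count draws, less Monte-Carlo noise); the
    band and SD come from whichever draw set ``band`` selects.
    """
    if band == "expected":
        src, discrete = lam_draws, False
    elif band == "predictive":
        src, discrete = (count_draws if count_draws is not None
                         else lam_draws), count_draws is not None
    else:
        raise ValueError(f"unknown band {band!r}")
    lo, hi = _interval_from_samples(src, discrete)
    return ProjectionResult(
        np.asarray(years), np.asarray(ages),
        lam_draws.mean(axis=0), src.std(axis=0, ddof=1), lo, hi,
        count_draws if (keep_samples and count_draws is not None) else None,
        model, band,
    )


def _future_years(t: RegistryTable, horizon: int) -> np.ndarray:
    return t.years[-1] + 1 + np.arange(horizon)


def _check_future_N(future_N, horizon: int, n_ages: int) -> np.ndarray:
    if future_N is None:
        raise ValueError("future_N is required")
    N = np.atleast_2d(np.asarray(future_N, dtype=float))
    if N.shape != (horizon, n_ages):
        raise ValueError(f"future_N shape {N.shape} != ({horizon}, {n_ages})")
    if np.any(~(N > 0)):
        raise ValueError("future_N must be strictly positive")
    return N


# ---------------------------------------------------------------------
# constant forward projection
# ---------------------------------------------------------------------


class ConstantProjector(BaseEstimator):
    """Carry the last observed year forward, as rates or as counts.

    ``mode="rate"`` scales the final year's rates by future person-years
    (``mode="count"`` repeats the final counts verbatim).  The predictive
    distribution is degenerate: the interval collapses to the point and
    the predictive SD is zero.
    """

    def __init__(self, mode: str = "rate"):
        self.mode = mode

    def fit(self, t: RegistryTable) -> "ConstantProjector":
        if self.mode not in ("rate", "count"):
            raise ValueError("mode must be 'rate' or 'count'")
        if t.n_years < 1:
            raise ValueError("empty table")
        self.table_ = t
        self.last_rate_ = t.incidence[-1] / t.population[-1]
        self.last_count_ = t.incidence[-1].astype(float)
        self.converged_ = True
        return self

    def project(self, future_N=None, horizon: int = 1, n_samples: int = 1000,
                seed: int = 0, keep_samples: bool = False,
                band: str = "predictive") -> ProjectionResult:
        t = self.table_
        if self.mode == "rate":
            N = _check_future_N(future_N, horizon, t.n_ages)
            point = self.last_rate_[None, :] * N
        else:
            point = np.tile(self.last_count_, (horizon, 1))
        zeros = np.zeros_like(point)
        samples = None
        if keep_samples:
            samples = np.broadcast_to(point, (n_samples, *point.shape)).copy()
        return ProjectionResult(
            _future_years(t, horizon), t.age_lower, point, zeros,
            point.copy(), point.copy(), samples,
            f"constant_{self.mode}", band,
        )


# ---------------------------------------------------------------------
# fixed-effect GLM / GAM machinery
# ---------------------------------------------------------------------


def _unroll(t: RegistryTable):
    """Flatten (year, age) cells row-major; return y, N, age mids, years."""
    J, I = t.n_years, t.n_ages
    y = t.incidence.reshape(J * I).astype(float)
    N = t.population.reshape(J * I)
    ages = np.tile(t.age_mid, J)
    years = np.repeat(t.years.astype(float), I)
    return y, N, ages, years


class _FixedEffectModel(BaseEstimator):
    """Shared fit/project plumbing for NB models with fixed-effect designs.

    Subclasses implement ``_design(ages, years)`` returning the design
    matrix for arbitrary (age, year) cells; covariates are centred at
    the training means so interaction fits stay numerically stable.
    ``engine='ml'`` obtains maximum-likelihood estimates (negative
    binomial with dispersion estimated, via statsmodels) and projects by
    plugging the MLE into the NB predictive (no parameter uncertainty);
    ``engine='bayes'`` uses the latent Gaussian engine with a vague
    Gaussian prior on the coefficients, giving a posterior predictive.
    """

    engine: str = "ml"
    family: str = "negative_binomial"

    def _design(self, ages: np.ndarray, years: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def fit(self, t: RegistryTable):
        y, N, ages, years = _unroll(t)
        self.table_ = t
        self.age_center_ = ages.mean()
        self.year_center_ = years.mean()
        X = self._design(ages, years)
        if X.shape[1] > X.shape[0]:
            raise ValueError("design has more columns than cells")
        if self.engine == "ml":
            self._fit_ml(y, X, N)
        elif self.engine == "bayes":
            self._fit_bayes(y, X, N)
        else:
            raise ValueError(f"unknown engine {self.engine!r}")
        return self

    def _fit_ml(self, y, X, N):
        import statsmodels.api as sm

        if self.family == "negative_binomial":
            mod = sm.NegativeBinomial(y, X, exposure=N, loglike_method="nb2")
            try:
                with np.errstate(all="ignore"):
                    res = mod.fit(disp=0, maxiter=200, method="bfgs")
                params = res.params
                converged = bool(res.mle_retvals.get("converged", True))
                alpha = float(max(params[-1], 0.0))
                beta = params[:-1]
                llf = float(res.llf)
            except Exception:
                converged = False
                alpha, beta, llf = None, None, None
            if beta is None or not np.all(np.isfinite(beta)):
                # Poisson-limit fallback when the NB dispersion degenerates
                pois = sm.GLM(y, X, exposure=N,
                              family=sm.families.Poisson()).fit()
                beta, alpha, llf = pois.params, 0.0, float(pois.llf)
                converged = bool(pois.converged)
        else:
            pois = sm.GLM(y, X, exposure=N, family=sm.families.Poisson()).fit()
            beta, alpha, llf = pois.params, 0.0, float(pois.llf)
            converged = bool(pois.converged)
        self.coef_ = np.asarray(beta, dtype=float)
        self.alpha_ = float(alpha)
        self.loglik_ = llf
        self.converged_ = converged

    def _fit_bayes(self, y, X, N):
        problem = eng.LatentGaussianProblem(
            y=y, offset=np.log(N), X=X, blocks=[], family=self.family)
        self.posterior_ = eng.fit_latent_gaussian(
            problem, seed=getattr(self, "seed", 0) or 0,
            n_draws=getattr(self, "n_draws", 2000))
        self.coef_ = self.posterior_.u_draws.mean(axis=0)
        self.converged_ = bool(self.posterior_.diagnostics.get("converged", True))

    def project(self, future_N=None, horizon: int = 1, n_samples: int = 1000,
                seed: int = 0, keep_samples: bool = False,
                band: str = "predictive") -> ProjectionResult:
        t = self.table_
        N = _check_future_N(future_N, horizon, t.n_ages)
        years = _future_years(t, horizon)
        ages = np.tile(t.age_mid, horizon)
        yrs = np.repeat(years.astype(float), t.n_ages)
        X = self._design(ages, yrs)
        shape = (horizon, t.n_ages)
        if self.engine == "bayes":
            # same seed -> identical latent draws under both calls, so the
            # count draws are the expected-count draws plus observation noise
            S = max(n_samples, 100)
            off = np.log(N).reshape(-1)
            lam = eng.posterior_predictive(
                self.posterior_, X, off, n_samples=S, seed=seed,
                observation_noise=False).reshape(-1, *shape)
            counts = eng.posterior_predictive(
                self.posterior_, X, off, n_samples=S, seed=seed,
                observation_noise=True).reshape(-1, *shape)
            return _summaries(lam, counts, years, t.age_lower,
                              type(self).__name__, band, keep_samples)
        mu = (np.exp(X @ self.coef_) * N.reshape(-1)).reshape(shape)
        if band == "expected":
            # plug-in MLE: no parameter uncertainty, degenerate band
            sd, lo, hi = np.zeros_like(mu), mu.copy(), mu.copy()
        elif self.alpha_ > 1e-10:
            size = 1.0 / self.alpha_
            p = size / (size + mu)
            sd = np.sqrt(mu + self.alpha_ * mu**2)
            lo = stats.nbinom.ppf(0.025, size, p)
            hi = stats.nbinom.ppf(0.975, size, p)
        else:
            sd = np.sqrt(mu)
            lo = stats.poisson.ppf(0.025, mu)
            hi = stats.poisson.ppf(0.975, mu)
        samples = None
        if keep_samples:
            rng = np.random.default_rng(seed)
            S = max(n_samples, 100)
            if self.alpha_ > 1e-10:
                size = 1.0 / self.alpha_
                p = size / (size + mu)
                samples = rng.negative_binomial(
                    size, p, size=(S, *shape)).astype(float)
            else:
                samples = rng.poisson(mu, size=(S, *shape)).astype(float)
        return ProjectionResult(years, t.age_lower, mu, sd, lo, hi,
                                samples, type(self).__name__, band)


class GLMProjector(_FixedEffectModel):
    """Negative-binomial GLM on the log-rate scale.

    ``terms="intercept"`` fits the intercept-only model (one common rate
    across all cells); ``terms="age_period_interaction"`` fits linear
    age, linear period and their interaction.  Covariates enter as
    numeric midpoints centred at training means.
    """

    def __init__(self, terms: str = "age_period_interaction",
                 engine: str = "ml", family: str = "negative_binomial",
                 seed: int = 0, n_draws: int = 2000):
        self.terms = terms
        self.engine = engine
        self.family = family
        self.seed = seed
        self.n_draws = n_draws

    def _design(self, ages, years):
        one = np.ones_like(ages)
        if self.terms == "intercept":
            return one[:, None]
        if self.terms == "age_period_interaction":
            a = ages - self.age_center_
            p = years - self.year_center_
            return np.column_stack([one, a, p, a * p])
        raise ValueError(f"unknown terms {self.terms!r}")


class AgeSplineGAMProjector(_FixedEffectModel):
    """GAM with a B-spline smooth in age and a linear period effect.

    The spline basis spans the training age range (ages never leave it
    at projection time); the basis replaces the intercept, so the design
    is ``[B-spline(age) | centred period]``.  With ``degree=0`` and one
    basis function per age group the model is saturated in age and
    reproduces per-age mean rates.
    """

    def __init__(self, n_basis: int | None = None, degree: int = 3,
                 engine: str = "ml", family: str = "negative_binomial",
                 period_term: bool = True, seed: int = 0, n_draws: int = 2000):
        self.n_basis = n_basis
        self.degree = degree
        self.engine = engine
        self.family = family
        self.period_term = period_term
        self.seed = seed
        self.n_draws = n_draws

    def fit(self, t: RegistryTable):
        if t.n_ages < 2:
            raise ValueError("age spline needs at least two age groups")
        q = self.n_basis or min(10, math.ceil(t.n_ages / 2) + 2)
        if q > t.n_ages:
            raise ValueError(f"n_basis={q} exceeds number of age groups {t.n_ages}")
        self.n_basis_ = q
        self.age_span_ = (float(t.age_mid.min()), float(t.age_mid.max()))
        return super().fit(t)

    def _design(self, ages, years):
        B = bas.bspline_basis(ages, self.n_basis_, self.degree,
                              span=self.age_span_)
        if not self.period_term:
            return B.values
        p = years - self.year_center_
        return np.column_stack([B.values, p])


# ---------------------------------------------------------------------
# Bayesian tensor-product smoother (z-model)
# ---------------------------------------------------------------------


class TensorSmootherProjector(BaseEstimator):
    """Bayesian smooth age x period surface as a random-effects z-model.

    The linear predictor is ``eta = mu + Z z`` where ``Z`` is the
    row-wise Kronecker product of M-spline marginal bases in age and
    period and ``z ~ N(0, tau^-1 I)`` with a Gamma(a, b) prior on the
    precision ``tau`` (default a=1, b=0.005).  Counts are negative
    binomial with a log person-years offset.  The period basis is built
    over the training span extended by ``max_horizon`` years so the
    smooth surface can be evaluated at projection cells; beyond the
    data the prior shrinks the surface toward the intercept with
    widening uncertainty.
    """

    def __init__(self, n_basis_age: int | None = None,
                 n_basis_period: int | None = None, degree: int = 3,
                 prior: tuple[float, float] = (1.0, 0.005),
                 max_horizon: int = 20, seed: int = 0, n_draws: int = 2000):
        self.n_basis_age = n_basis_age
        self.n_basis_period = n_basis_period
        self.degree = degree
        self.prior = prior
        self.max_horizon = max_horizon
        self.seed = seed
        self.n_draws = n_draws

    def _bases(self, ages, years):
        A = bas.mspline_basis(ages, self.qa_, self.degree, span=self.age_span_)
        P = bas.mspline_basis(years, self.qp_, self.degree,
                              span=self.period_span_)
        return bas.tensor_product_rows(A, P).values

    def fit(self, t: RegistryTable):
        y, N, ages, years = _unroll(t)
        self.table_ = t
        self.qa_ = self.n_basis_age or min(10, math.ceil(t.n_ages / 2) + 2)
        self.qp_ = self.n_basis_period or min(8, math.ceil(t.n_years / 2) + 2)
        self.age_span_ = (float(t.age_mid.min()), float(t.age_mid.max()))
        self.period_span_ = (float(t.years.min()),
                             float(t.years.max() + self.max_horizon))
        Z = self._bases(ages, years)
        if Z.shape[0] != y.size:
            raise ValueError("tensor basis rows do not match unrolled table")
        block = eng.RandomEffectBlock(
            design=Z, structure=bas.iid_structure(Z.shape[1]),
            prior=self.prior, name="tensor_z")
        problem = eng.LatentGaussianProblem(
            y=y, offset=np.log(N), X=np.ones((y.size, 1)), blocks=[block],
            family="negative_binomial")
        self.posterior_ = eng.fit_latent_gaussian(
            problem, seed=self.seed, n_draws=self.n_draws)
        self.converged_ = bool(self.posterior_.diagnostics.get("converged", True))
        return self

    def project(self, future_N=None, horizon: int = 1, n_samples: int = 1000,
                seed: int = 0, keep_samples: bool = False,
                band: str = "predictive") -> ProjectionResult:
        t = self.table_
        if horizon > self.max_horizon:
            raise ValueError(f"horizon {horizon} exceeds max_horizon "
                             f"{self.max_horizon} set before fitting")
        N = _check_future_N(future_N, horizon, t.n_ages)
        years = _future_years(t, horizon)
        ages = np.tile(t.age_mid, horizon)
        yrs = np.repeat(years.astype(float), t.n_ages)
        Z = self._bases(ages, yrs)
        rows = np.column_stack([np.ones(Z.shape[0]), Z])
        S = max(n_samples, 100)
        off = np.log(N).reshape(-1)
        lam = eng.posterior_predictive(
            self.posterior_, rows, off, n_samples=S, seed=seed,
            observation_noise=False).reshape(-1, horizon, t.n_ages)
        counts = eng.posterior_predictive(
            self.posterior_, rows, off, n_samples=S, seed=seed,
            observation_noise=True).reshape(-1, horizon, t.n_ages)
        return _summaries(lam, counts, years, t.age_lower, "tensor_z",
                          band, keep_samples)


# ---------------------------------------------------------------------
# Bayesian age-period-cohort model
# ---------------------------------------------------------------------


class BAPCProjector(BaseEstimator):
    """Bayesian APC model with rw2 effects and iid overdispersion.

    The log rate of cell (age group i, period j) is

        eta_ij = mu + alpha_i + beta_j + gamma_k + epsilon_ij,
        k = j + M (I - i),

    with second-order random-walk priors on the age, period and cohort
    effect vectors, an iid overdispersion effect epsilon, a Poisson
    likelihood, and Gamma priors on all four precisions.  Sum-to-zero
    constraints identify the effects up to the well-known shared linear
    trend; the cohort effect's linear component is additionally removed
    so the posterior is proper (the linear predictor eta, the only
    reported estimand, is unaffected).  Projection extends the period
    and cohort random walks beyond the grid by sampling their rw2
    predictive (locally linear trend with growing variance) and draws
    fresh overdispersion effects per future cell.
    """

    def __init__(self, prior: tuple[float, float] = (1.0, 0.005),
                 constrain_cohort_trend: bool = True, seed: int = 0,
                 n_draws: int = 2000, maxfev: int | None = None):
        self.prior = prior
        self.constrain_cohort_trend = constrain_cohort_trend
        self.seed = seed
        self.n_draws = n_draws
        self.maxfev = maxfev

    def fit(self, t: RegistryTable):
        lex = t.lexis
        if lex.I < 3 or lex.J < 3:
            raise ValueError("rw2 effects need at least 3 age groups and periods")
        self.table_ = t
        self.lexis_ = lex
        y, N, _, _ = _unroll(t)
        J, I, K = lex.J, lex.I, lex.K
        n = J * I
        age_Z = np.zeros((n, I))
        per_Z = np.zeros((n, J))
        coh_Z = np.zeros((n, K))
        for j in range(J):
            for i in range(I):
                c = j * I + i
                age_Z[c, i] = 1.0
                per_Z[c, j] = 1.0
                coh_Z[c, cohort_index(lex, i + 1, j + 1) - 1] = 1.0
        coh_con = [eng.sum_to_zero_constraint(K)]
        if self.constrain_cohort_trend:
            coh_con.append(eng.linear_trend_constraint(K))
        blocks = [
            eng.RandomEffectBlock(age_Z, bas.rw2_structure(I), self.prior,
                                  eng.sum_to_zero_constraint(I), "age"),
            eng.RandomEffectBlock(per_Z, bas.rw2_structure(J), self.prior,
                                  eng.sum_to_zero_constraint(J), "period"),
            eng.RandomEffectBlock(coh_Z, bas.rw2_structure(K), self.prior,
                                  np.vstack(coh_con), "cohort"),
            eng.RandomEffectBlock(np.eye(n), bas.iid_structure(n), self.prior,
                                  None, "overdispersion"),
        ]
        problem = eng.LatentGaussianProblem(
            y=y, offset=np.log(N), X=np.ones((n, 1)), blocks=blocks,
            family="poisson")
        self.posterior_ = eng.fit_latent_gaussian(
            problem, seed=self.seed, n_draws=self.n_draws, maxfev=self.maxfev)
        self.converged_ = bool(self.posterior_.diagnostics.get("converged", True))
        return self

    def linpred_summary(self):
        """Posterior mean and SD of eta (without offset) on the training grid."""
        pa = self.posterior_
        d = pa.linpred_draws() - pa.problem.offset
        J, I = self.lexis_.J, self.lexis_.I
        return (d.mean(axis=0).reshape(J, I), d.std(axis=0, ddof=1).reshape(J, I))

    def project(self, future_N=None, horizon: int = 1, n_samples: int = 1000,
                seed: int = 0, keep_samples: bool = False,
                band: str = "predictive") -> ProjectionResult:
        t, lex, pa = self.table_, self.lexis_, self.posterior_
        I, J, K, M = lex.I, lex.J, lex.K, lex.M
        N = _check_future_N(future_N, horizon, t.n_ages)
        rng = np.random.default_rng(seed)
        S = max(n_samples, 100)
        idx = rng.integers(0, pa.n_draws, size=S)
        mu = pa.u_draws[idx, pa.fixed_slice()][:, 0]
        alpha = pa.u_draws[idx][:, pa.block_slice("age")]
        beta = pa.u_draws[idx][:, pa.block_slice("period")]
        gamma = pa.u_draws[idx][:, pa.block_slice("cohort")]
        tau = np.exp(pa.theta_draws[idx])  # (S, 4): age, period, cohort, iid
        tau_per, tau_coh, tau_iid = tau[:, 1], tau[:, 2], tau[:, 3]

        beta_ext = _extend_rw2(beta, horizon, tau_per, rng)
        gamma_ext = _extend_rw2(gamma, horizon, tau_coh, rng)
        lam = np.empty((S, horizon, I))
        counts = np.empty((S, horizon, I))
        for h in range(horizon):
            j = J + 1 + h  # 1-based future period index
            for i0 in range(I):
                k = j + M * (I - (i0 + 1))  # 1-based cohort index
                eta = (mu + alpha[:, i0] + beta_ext[:, j - 1]
                       + gamma_ext[:, k - 1]
                       + rng.standard_normal(S) / np.sqrt(tau_iid))
                lam[:, h, i0] = np.exp(
                    np.clip(eta + math.log(N[h, i0]), -40.0, 40.0))
                counts[:, h, i0] = rng.poisson(lam[:, h, i0])
        return _summaries(lam, counts, _future_years(t, horizon), t.age_lower,
                          "bapc", band, keep_samples)


def _extend_rw2(z: np.ndarray, steps: int, tau: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Continue rw2 vectors forward: each step doubles back on the local
    linear trend plus innovation noise with per-draw precision ``tau``."""
    S, n = z.shape
    out = np.empty((S, n + steps))
    out[:, :n] = z
    sd = 1.0 / np.sqrt(tau)
    for s in range(steps):
        out[:, n + s] = (2 * out[:, n + s - 1] - out[:, n + s - 2]
                         + sd * rng.standard_normal(S))
    return out


# ---------------------------------------------------------------------
# registry of model constructors + thin functional wrappers
# ---------------------------------------------------------------------

# benchmark defaults: GLMs/GAMs are fitted with the Bayes engine so their
# bands carry parameter uncertainty; engine="ml" remains selectable
MODEL_REGISTRY = {
    "constant_rate": lambda **kw: ConstantProjector(mode="rate"),
    "constant_count": lambda **kw: ConstantProjector(mode="count"),
    "glm_intercept": lambda **kw: GLMProjector(
        terms="intercept", **{"engine": "bayes", **kw}),
    "glm_age_period": lambda **kw: GLMProjector(
        terms="age_period_interaction", **{"engine": "bayes", **kw}),
    "gam_age_spline": lambda **kw: AgeSplineGAMProjector(
        **{"engine": "bayes", **kw}),
    "tensor_z": lambda **kw: TensorSmootherProjector(**kw),
    "bapc": lambda **kw: BAPCProjector(**kw),
}


def make_projector(name: str, **options):
    """Instantiate a model from the ladder by name."""
    try:
        ctor = MODEL_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose from {sorted(MODEL_REGISTRY)}"
        ) from None
    return ctor(**options)


def project_constant(t: RegistryTable, mode: str = "rate", future_N=None,
                     horizon: int = 1) -> ProjectionResult:
    return ConstantProjector(mode=mode).fit(t).project(future_N, horizon)


def fit_glm(t: RegistryTable, terms: str = "age_period_interaction",
            engine: str = "ml", **kw) -> GLMProjector:
    return GLMProjector(terms=terms, engine=engine, **kw).fit(t)


def fit_gam_age_spline(t: RegistryTable, n_basis: int | None = None,
                       engine: str = "ml", **kw) -> AgeSplineGAMProjector:
    return AgeSplineGAMProjector(n_basis=n_basis, engine=engine, **kw).fit(t)


def fit_tensor_z(t: RegistryTable, **kw) -> TensorSmootherProjector:
    return TensorSmootherProjector(**kw).fit(t)


def fit_bapc(t: RegistryTable, **kw) -> BAPCProjector:
    return BAPCProjector(**kw).fit(t)


def project(fit, future_N=None, horizon: int = 1, n_samples: int = 1000,
            seed: int = 0, keep_samples: bool = False,
            band: str = "predictive") -> ProjectionResult:
    """Project a fitted model; thin wrapper over ``fit.project``."""
    return fit.project(future_N=future_N, horizon=horizon,
                       n_samples=n_samples, seed=seed,
                       keep_samples=keep_samples, band=band)
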