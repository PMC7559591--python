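"""Synthetic registry tables with known age-period-cohort structure.

The generator emulates the layout and magnitudes of population-based
cancer-registry extracts: 5-year age groups from age 20 to 84, a few
decades of annual data, per-cell rates between roughly 1e-5 and 1e-2,
and populations of order 1e5 person-years per age group.  The log rate
decomposes as

    eta_ij = base + f_age(a_i) + drift * (t_j - t_mid)
             + interaction * s(a_i) * s(t_j) + g_cohort(k)

with a parametric age curve, a log-linear period drift, an optional
multiplicative age x period interaction and a smooth cohort curve
generated as a doubly integrated (rw2-like) noise process indexed by
``k = j + M (I - i)`` so the generative geometry matches the cohort
model exactly.  Counts are Poisson or negative binomial around
``N_ij * exp(eta_ij)``; the true rate surface and effect vectors are
returned for parameter-recovery and calibration studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .registry import LexisSpec, RegistryTable

__all__ = ["SyntheticSpec", "simulate", "scenario_library",
           "simulate_bapc_generative"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic registry.

    Age-curve kinds: ``log_quadratic`` (coefficients on standardized
    age and its square — the registry-typical monotone rise) or
    ``gaussian_bump`` (amplitude, centre, width in years).
    """

    start_year: int = 1980
    n_years: int = 35
    age_start: int = 20
    n_ages: int = 13
    age_width: int = 5
    base_log_rate: float = -8.0  # ~3.4e-4 cases per person-year
    age_curve: str = "log_quadratic"
    age_coef: tuple[float, float] = (1.6, -0.35)
    bump: tuple[float, float, float] = (1.0, 55.0, 12.0)
    drift: float = 0.0  # log-rate change per year
    interaction: float = 0.0  # coefficient on s(age) * s(period)
    cohort_amplitude: float = 0.0  # max |cohort effect| on the log scale
    cohort_roughness: float = 1.0  # relative rw2 innovation scale
    noise: str = "poisson"  # poisson | negative_binomial
    nb_size: float = 20.0  # NB size; var = mu + mu^2/size
    pop_start: float = 2.0e5  # person-years in the youngest group, year 1
    pop_age_slope: float = -0.012  # log population change per year of age
    pop_growth: float = 0.004  # annual log population growth
    seed: int = 0
    name: str = "synthetic"


def _age_effect(spec: SyntheticSpec, age_mid: np.ndarray) -> np.ndarray:
    s = (age_mid - age_mid.mean()) / age_mid.std()
    if spec.age_curve == "log_quadratic":
        b1, b2 = spec.age_coef
        return b1 * s + b2 * s * s
    if spec.age_curve == "gaussian_bump":
        amp, centre, width = spec.bump
        return amp * np.exp(-0.5 * ((age_mid - centre) / width) ** 2)
    raise ValueError(f"unknown age_curve {spec.age_curve!r}")


def _cohort_effect(spec: SyntheticSpec, K: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth rw2-like curve: doubly integrated noise, detrended and
    scaled to the requested amplitude."""
    if spec.cohort_amplitude == 0.0:
        return np.zeros(K)
    inc = rng.standard_normal(K) * spec.cohort_roughness
    curve = np.cumsum(np.cumsum(inc))
    x = np.arange(K, dtype=float)
    X = np.column_stack([np.ones(K), x - x.mean()])
    curve = curve - X @ np.linalg.lstsq(X, curve, rcond=None)[0]
    peak = np.abs(curve).max()
    if peak > 0:
        curve *= spec.cohort_amplitude / peak
    return curve


def simulate(spec: SyntheticSpec) -> tuple[RegistryTable, dict]:
    """Draw one registry table; return it with the generative truth.

    The truth dict holds the log-rate surface ``eta`` (years x ages),
    the rate surface, and the age/period/cohort effect components.
    """
    rng = np.random.default_rng(spec.seed)
    I, J, M = spec.n_ages, spec.n_years, spec.age_width
    lex = LexisSpec(I=I, J=J, M=M)
    years = spec.start_year + np.arange(J)
    age_lower = spec.age_start + spec.age_width * np.arange(I)
    age_mid = age_lower + (spec.age_width - 1) / 2.0

    f_age = _age_effect(spec, age_mid)
    t_rel = years - years.mean()
    f_per = spec.drift * t_rel
    g_coh = _cohort_effect(spec, lex.K, rng)
    s_age = (age_mid - age_mid.mean()) / age_mid.std()
    s_per = t_rel / max(t_rel.std(), 1e-12)

    eta = np.empty((J, I))
    for j in range(J):
        for i in range(I):
            k = (j + 1) + M * (I - (i + 1))  # 1-based cohort index
            eta[j, i] = (spec.base_log_rate + f_age[i] + f_per[j]
                         + spec.interaction * s_age[i] * s_per[j]
                         + g_coh[k - 1])
    rate = np.exp(eta)
    bad = np.argwhere(rate >= 1.0)
    if len(bad):
        j, i = bad[0]
        raise ValueError(
            f"rate >= 1 at year {years[j]}, age group {age_lower[i]} "
            f"(rate {rate[j, i]:.3g}); lower the effect sizes"
        )

    pop_age = spec.pop_start * np.exp(spec.pop_age_slope * (age_mid - age_mid[0]))
    N = pop_age[None, :] * np.exp(spec.pop_growth * np.arange(J))[:, None]
    mu = N * rate
    if spec.noise == "poisson":
        Y = rng.poisson(mu)
    elif spec.noise == "negative_binomial":
        lam = rng.gamma(spec.nb_size, mu / spec.nb_size)
        Y = rng.poisson(lam)
    else:
        raise ValueError(f"unknown noise {spec.noise!r}")

    table = RegistryTable(
        years=years, age_lower=age_lower, age_width=spec.age_width,
        incidence=Y, population=N, meta={"scenario": spec.name},
    )
    truth = {
        "eta": eta, "rate": rate, "age_effect": f_age,
        "period_effect": f_per, "cohort_effect": g_coh, "lexis": lex,
    }
    return table, truth


def simulate_bapc_generative(
    I: int = 5,
    J: int = 12,
    M: int = 1,
    mu: float = -7.0,
    tau_age: float = 10.0,
    tau_period: float = 100.0,
    tau_cohort: float = 100.0,
    tau_overdispersion: float = 400.0,
    N0: float = 5.0e4,
    start_year: int = 2000,
    age_start: int = 40,
    seed: int = 0,
) -> tuple[RegistryTable, dict]:
    """Draw a registry directly from the cohort model's generative process.

    Age, period and cohort effect vectors are second-order random walks
    (doubly integrated Gaussian innovations with precision ``tau_*``,
    sum-to-zero, cohort additionally detrended to match the fitted
    model's identification), an iid overdispersion effect is added per
    cell, and counts are Poisson.  Used for self-consistency and
    band-calibration studies: a correctly implemented fit of the same
    model to such tables should produce calibrated predictive bands.
    """
    rng = np.random.default_rng(seed)
    lex = LexisSpec(I=I, J=J, M=M)

    def rw2(m: int, tau: float, detrend: bool) -> np.ndarray:
        z = np.cumsum(np.cumsum(rng.standard_normal(m) / np.sqrt(tau)))
        x = np.arange(m, dtype=float)
        cols = [np.ones(m)] + ([x - x.mean()] if detrend else [])
        X = np.column_stack(cols)
        return z - X @ np.linalg.lstsq(X, z, rcond=None)[0]

    alpha = rw2(I, tau_age, detrend=False)
    beta = rw2(J, tau_period, detrend=False)
    gamma = rw2(lex.K, tau_cohort, detrend=True)
    eps = rng.standard_normal((J, I)) / np.sqrt(tau_overdispersion)
    eta = np.empty((J, I))
    for j in range(J):
        for i in range(I):
            k = (j + 1) + M * (I - (i + 1))
            eta[j, i] = mu + alpha[i] + beta[j] + gamma[k - 1] + eps[j, i]
    N = np.full((J, I), float(N0))
    Y = rng.poisson(N * np.exp(eta))
    table = RegistryTable(
        years=start_year + np.arange(J),
        age_lower=age_start + M * np.arange(I),
        age_width=M if M in (1, 5) else 1,
        incidence=Y, population=N, meta={"scenario": "bapc-generative"},
    )
    truth = {"eta": eta, "alpha": alpha, "beta": beta, "gamma": gamma,
             "mu": mu, "lexis": lex}
    return table, truth


def scenario_library() -> dict[str, SyntheticSpec]:
    """Named scenarios spanning the model ladder.

    Each non-constant model in the ladder is the (approximately) true
    model for one scenario: intercept-only for "flat", the age-smooth
    GAM for "age-only", GLM/GAM drift terms for "age+drift", the tensor
    smoother for "age-period-interaction", the cohort model for
    "full-apc", and the NB variants for "overdispersed".
    """
    base = SyntheticSpec()
    lib = {
        "flat": replace(base, name="flat", age_coef=(0.0, 0.0)),
        "age-only": replace(base, name="age-only"),
        "age+drift": replace(base, name="age+drift", drift=0.015),
        "age-period-interaction": replace(
            base, name="age-period-interaction", drift=0.01, interaction=0.25),
        "full-apc": replace(
            base, name="full-apc", drift=0.015, cohort_amplitude=0.3),
        "overdispersed": replace(
            base, name="overdispersed", drift=0.015, cohort_amplitude=0.3,
            noise="negative_binomial", nb_size=20.0),
    }
    return lib
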