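"""The projection-model ladder: closed forms, recovery, extrapolation."""

import numpy as np
import pytest

from incproj.models import (
    AgeSplineGAMProjector,
    BAPCProjector,
    ConstantProjector,
    GLMProjector,
    TensorSmootherProjector,
    make_projector,
    project_constant,
)
from incproj.registry import RegistryTable, cohort_index
from incproj.synthetic import SyntheticSpec, simulate, simulate_bapc_generative

from conftest import random_table


def flat_table(rate=4e-4, n_years=8, n_ages=5, N0=1e5, seed=0):
    rng = np.random.default_rng(seed)
    N = np.full((n_years, n_ages), N0)
    Y = rng.poisson(rate * N)
    return RegistryTable(years=2000 + np.arange(n_years),
                         age_lower=20 + 5 * np.arange(n_ages), age_width=5,
                         incidence=Y, population=N)


class TestConstantProjector:
    def test_rate_mode_scales_with_future_population(self):
        t = random_table(np.random.default_rng(0), n_years=3, n_ages=1)
        t2 = RegistryTable(years=t.years, age_lower=t.age_lower,
                           age_width=t.age_width,
                           incidence=[[5], [7], [10]],
                           population=[[100.0], [100.0], [100.0]])
        proj = project_constant(t2, mode="rate", future_N=[[200.0]], horizon=1)
        assert proj.mean[0, 0] == pytest.approx(20.0)
        assert proj.sd[0, 0] == 0.0
        assert proj.lo[0, 0] == proj.hi[0, 0] == proj.mean[0, 0]

    def test_count_mode_repeats_last_row(self, small_table):
        proj = project_constant(small_table, mode="count", horizon=3)
        for h in range(3):
            np.testing.assert_allclose(proj.mean[h],
                                       small_table.incidence[-1])

    def test_per_age_outputs_match_scalar_loop(self, rng):
        t = random_table(rng, n_years=4, n_ages=3)
        N_fut = rng.uniform(5e4, 1e5, size=(2, 3))
        proj = project_constant(t, mode="rate", future_N=N_fut, horizon=2)
        for h in range(2):
            for a in range(3):
                expect = (t.incidence[-1, a] / t.population[-1, a]) * N_fut[h, a]
                assert proj.mean[h, a] == pytest.approx(expect)

    def test_empty_table_rejected(self):
        with pytest.raises(Exception):
            ConstantProjector().fit(None)


class TestGLMClosedForms:
    @pytest.mark.parametrize("case", range(10))
    def test_poisson_intercept_mle_is_overall_rate(self, case):
        rng = np.random.default_rng(1000 + case)
        t = random_table(rng, n_years=int(rng.integers(3, 8)),
                         n_ages=int(rng.integers(2, 6)))
        m = GLMProjector(terms="intercept", engine="ml",
                         family="poisson").fit(t)
        expect = t.incidence.sum() / t.population.sum()
        assert np.exp(m.coef_[0]) == pytest.approx(expect, rel=1e-6)

    @pytest.mark.parametrize("case", range(5))
    def test_nb_intercept_mle_on_constant_population(self, case):
        rng = np.random.default_rng(2000 + case)
        t = random_table(rng, constant_N=True)
        m = GLMProjector(terms="intercept", engine="ml").fit(t)
        expect = t.incidence.sum() / t.population.sum()
        assert np.exp(m.coef_[0]) == pytest.approx(expect, rel=1e-6)

    def test_simulated_coefficients_recovered_within_3_se(self):
        # eta = b0 + b1*age_c with b=(-8, 0.05, 0, 0) at large N
        rng = np.random.default_rng(7)
        n_years, n_ages = 10, 10
        years = 1990 + np.arange(n_years)
        ages = 20 + 5 * np.arange(n_ages)
        mids = ages + 2.0
        N = np.full((n_years, n_ages), 5e5)
        a_c = mids - np.tile(mids, n_years).mean()
        eta = -8.0 + 0.05 * a_c
        Y = rng.poisson(N * np.exp(eta)[None, :])
        t = RegistryTable(years=years, age_lower=ages, age_width=5,
                          incidence=Y, population=N)
        m = GLMProjector(terms="age_period_interaction", engine="ml").fit(t)
        import statsmodels.api as sm  # noqa: F401  (SEs via refit)
        truth = np.array([-8.0, 0.05, 0.0, 0.0])
        # SEs from the observed information of a Poisson refit (NB limit)
        y, Npop = Y.reshape(-1).astype(float), N.reshape(-1)
        X = m._design(np.tile(mids, n_years),
                      np.repeat(years.astype(float), n_ages))
        fit = sm.GLM(y, X, exposure=Npop, family=sm.families.Poisson()).fit()
        assert np.all(np.abs(m.coef_[:4] - truth) < 3 * fit.bse)

    def test_poisson_data_hits_nb_poisson_limit_and_converges(self):
        t = flat_table(N0=5e5, n_years=12)
        m = GLMProjector(terms="intercept", engine="ml").fit(t)
        assert m.converged_
        assert m.alpha_ < 0.01  # dispersion collapses toward Poisson

    def test_saturated_design_reproduces_observed_counts(self):
        # 2x2 grid, 4 parameters: fitted means equal observations exactly
        t = RegistryTable(years=[2000, 2001], age_lower=[40, 45], age_width=5,
                          incidence=[[30, 40], [50, 70]],
                          population=np.full((2, 2), 1e5))
        m = GLMProjector(terms="age_period_interaction", engine="ml",
                         family="poisson").fit(t)
        X = m._design(np.tile(t.age_mid, 2),
                      np.repeat(t.years.astype(float), 2))
        fitted = np.exp(X @ m.coef_) * t.population.reshape(-1)
        np.testing.assert_allclose(fitted, t.incidence.reshape(-1), rtol=1e-6)


class TestGAM:
    def test_degree0_saturated_fit_reproduces_per_age_mean_rates(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, n_years=6, n_ages=5, constant_N=True)
        m = AgeSplineGAMProjector(n_basis=5, degree=0, engine="ml",
                                  family="poisson", period_term=False).fit(t)
        proj = m.project(future_N=t.population[-1:], horizon=1)
        per_age_rate = t.incidence.sum(axis=0) / t.population.sum(axis=0)
        np.testing.assert_allclose(proj.mean[0],
                                   per_age_rate * t.population[-1],
                                   rtol=1e-6)

    def test_age_flat_truth_recovered_within_5_percent(self):
        t = flat_table(rate=6e-4, n_years=10, n_ages=8, N0=5e5, seed=11)
        m = AgeSplineGAMProjector(n_basis=6, engine="ml").fit(t)
        proj = m.project(future_N=t.population[-1:], horizon=1)
        truth = 6e-4 * t.population[-1]
        assert np.all(np.abs(proj.mean[0] - truth) / truth < 0.05)

    def test_single_age_column_rejected(self):
        t = random_table(np.random.default_rng(0), n_ages=1)
        with pytest.raises(ValueError):
            AgeSplineGAMProjector().fit(t)

    def test_n_basis_exceeding_age_count_rejected(self):
        t = random_table(np.random.default_rng(0), n_ages=4)
        with pytest.raises(ValueError, match="n_basis"):
            AgeSplineGAMProjector(n_basis=7).fit(t)


class TestTensorSmoother:
    def test_additive_truth_predictions_close_on_training_scale(self):
        spec = SyntheticSpec(n_years=15, drift=0.01, seed=21)
        t, truth = simulate(spec)
        m = TensorSmootherProjector(seed=1).fit(t)
        em, _ = m.posterior_.eta_summary()
        fitted = em - m.posterior_.problem.offset
        resid = fitted.reshape(t.n_years, t.n_ages) - truth["eta"]
        assert np.sqrt(np.mean(resid**2)) < 0.25

    def test_forced_tight_prior_collapses_to_intercept(self):
        spec = SyntheticSpec(n_years=12, seed=22)
        t, _ = simulate(spec)
        m = TensorSmootherProjector(prior=(1e6, 1.0), seed=2).fit(t)
        proj = m.project(future_N=t.population[-1:], horizon=1,
                         n_samples=500, seed=3, band="expected")
        rates_hat = proj.mean[0] / t.population[-1]
        # age structure flattened away: spread tiny vs the true 100x range
        assert rates_hat.max() / rates_hat.min() < 1.5

    def test_one_basis_per_margin_is_product_of_marginals(self):
        from incproj.basis import mspline_basis, tensor_product_rows
        x_a = np.array([0.2, 0.8])
        x_p = np.array([0.1, 0.9])
        A = mspline_basis(x_a, 1, degree=0, span=(0, 1))
        P = mspline_basis(x_p, 1, degree=0, span=(0, 1))
        Z = tensor_product_rows(A, P)
        assert Z.values.shape == (2, 1)
        np.testing.assert_allclose(Z.values[:, 0],
                                   A.values[:, 0] * P.values[:, 0])


class TestBAPC:
    def test_self_consistency_eta_within_3_sd_for_90pct_of_cells(self):
        table, truth = simulate_bapc_generative(I=5, J=10, seed=31)
        m = BAPCProjector(seed=32).fit(table)
        em, es = m.linpred_summary()
        z = np.abs(em - truth["eta"]) / es
        assert np.mean(z < 3.0) >= 0.90

    def test_constant_rate_large_counts_shrinks_to_overall_rate(self):
        t = flat_table(rate=5e-4, n_years=8, n_ages=5, N0=1e6, seed=33)
        m = BAPCProjector(seed=34).fit(t)
        proj = m.project(future_N=t.population[-1:], horizon=1,
                         n_samples=2000, seed=35)
        expect = (t.incidence.sum() / t.population.sum()) * t.population[-1]
        assert np.all(np.abs(proj.mean[0] - expect) / expect < 0.1)

    def test_linear_drift_reproduced_in_linear_predictor(self):
        rng = np.random.default_rng(36)
        n_years, n_ages = 10, 5
        N = np.full((n_years, n_ages), 5e5)
        drift = 0.03
        eta = -7.0 + drift * np.arange(n_years)[:, None]
        Y = rng.poisson(N * np.exp(eta))
        t = RegistryTable(years=2000 + np.arange(n_years),
                          age_lower=40 + np.arange(n_ages), age_width=1,
                          incidence=Y, population=N)
        m = BAPCProjector(seed=37).fit(t)
        em, _ = m.linpred_summary()
        slope = np.polyfit(np.arange(n_years), em.mean(axis=1), 1)[0]
        assert slope == pytest.approx(drift, abs=0.01)

    def test_effect_trend_shuffle_leaves_linear_predictor_unchanged(self):
        # moving a linear trend from alpha into beta/gamma is exactly
        # invisible in eta: the well-known APC identification problem
        lexmeta = simulate_bapc_generative(I=4, J=6, seed=38)[1]
        lex = lexmeta["lexis"]
        alpha, beta, gamma = lexmeta["alpha"], lexmeta["beta"], lexmeta["gamma"]
        delta = 0.07

        def eta_of(a, b, g):
            out = np.empty((lex.J, lex.I))
            for j in range(lex.J):
                for i in range(lex.I):
                    k = cohort_index(lex, i + 1, j + 1)
                    out[j, i] = a[i] + b[j] + g[k - 1]
            return out

        e0 = eta_of(alpha, beta, gamma)
        i_idx = np.arange(1, lex.I + 1)
        j_idx = np.arange(1, lex.J + 1)
        k_idx = np.arange(1, lex.K + 1)
        # alpha_i += d*M*i, gamma_k += d*k, beta_j -= d*(j + M*I)
        a2 = alpha + delta * lex.M * i_idx
        g2 = gamma + delta * k_idx
        b2 = beta - delta * (j_idx + lex.M * lex.I)
        e1 = eta_of(a2, b2, g2)
        np.testing.assert_allclose(e0, e1, atol=1e-10)

    def test_small_grids_rejected(self):
        t = flat_table(n_years=2, n_ages=5)
        with pytest.raises(ValueError):
            BAPCProjector().fit(t)


class TestProjection:
    def test_rw2_extension_variance_grows_with_horizon(self):
        table, _ = simulate_bapc_generative(I=5, J=12, seed=41)
        m = BAPCProjector(seed=42).fit(table)
        future_N = np.full((6, 5), 5e4)
        proj = m.project(future_N=future_N, horizon=6, n_samples=3000,
                         seed=43, band="expected")
        log_sd = np.log(proj.sd.mean(axis=1))
        assert np.all(np.diff(log_sd) > 0)

    def test_interval_width_shrinks_with_training_size(self):
        widths = []
        for n_years in (4, 16):
            t = flat_table(rate=5e-4, n_years=n_years, n_ages=3, N0=2e4,
                           seed=44)
            m = GLMProjector(terms="intercept", engine="bayes",
                             family="poisson", seed=45).fit(t)
            proj = m.project(future_N=t.population[-1:], horizon=1,
                             n_samples=3000, seed=46, band="expected")
            widths.append((proj.hi - proj.lo).mean())
            obs_rate = t.incidence.sum() / t.population.sum()
            lo_r = proj.lo[0] / t.population[-1]
            hi_r = proj.hi[0] / t.population[-1]
            assert np.all(lo_r < obs_rate) and np.all(obs_rate < hi_r)
        assert widths[1] < widths[0]

    @pytest.mark.parametrize("name", ["constant_rate", "glm_age_period",
                                      "gam_age_spline", "tensor_z", "bapc"])
    def test_doubling_future_population_doubles_predicted_counts(self, name):
        # the offset fixes projected rates; person-years only scale counts
        t = flat_table(rate=5e-4, n_years=10, n_ages=5, N0=1e5, seed=47)
        kw = {} if name.startswith("constant") else {"seed": 48}
        m = make_projector(name, **kw).fit(t)
        p1 = m.project(future_N=t.population[-1:], horizon=1,
                       n_samples=2000, seed=49, band="expected")
        p2 = m.project(future_N=2 * t.population[-1:], horizon=1,
                       n_samples=2000, seed=49, band="expected")
        ratio = p2.mean / p1.mean
        np.testing.assert_allclose(ratio, 2.0, rtol=0.06)

    def test_missing_future_population_rejected(self, small_table):
        m = ConstantProjector(mode="rate").fit(small_table)
        with pytest.raises(ValueError, match="future_N"):
            m.project(horizon=1)
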