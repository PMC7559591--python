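"""Latent Gaussian engine: conjugate oracles, constraints, predictive draws."""

import numpy as np
import pytest
from scipy import stats

from incproj import basis as bas
from incproj import engine as eng
from incproj.registry import LexisSpec, cohort_index


def bapc_fixture_problem(I=5, J=8, M=1, seed=42, N0=5e4):
    """Small age-period-cohort problem with known generative structure."""
    rng = np.random.default_rng(seed)
    lex = LexisSpec(I=I, J=J, M=M)
    n = I * J

    def rw2_draw(m, sd):
        z = np.cumsum(np.cumsum(sd * rng.standard_normal(m)))
        x = np.arange(m, dtype=float)
        X = np.column_stack([np.ones(m), x - x.mean()])
        return z - X @ np.linalg.lstsq(X, z, rcond=None)[0]

    alpha, beta = rw2_draw(I, 0.3), rw2_draw(J, 0.1)
    gamma = rw2_draw(lex.K, 0.1)
    N = np.full((J, I), N0)
    eta = np.empty((J, I))
    for j in range(J):
        for i in range(I):
            k = cohort_index(lex, i + 1, j + 1)
            eta[j, i] = (-7.0 + alpha[i] + beta[j] + gamma[k - 1]
                         + 0.1 * rng.standard_normal())
    y = rng.poisson(N * np.exp(eta)).reshape(-1).astype(float)
    age_Z = np.zeros((n, I))
    per_Z = np.zeros((n, J))
    coh_Z = np.zeros((n, lex.K))
    for j in range(J):
        for i in range(I):
            c = j * I + i
            age_Z[c, i] = 1
            per_Z[c, j] = 1
            coh_Z[c, cohort_index(lex, i + 1, j + 1) - 1] = 1
    blocks = [
        eng.RandomEffectBlock(age_Z, bas.rw2_structure(I), (1.0, 0.005),
                              eng.sum_to_zero_constraint(I), "age"),
        eng.RandomEffectBlock(per_Z, bas.rw2_structure(J), (1.0, 0.005),
                              eng.sum_to_zero_constraint(J), "period"),
        eng.RandomEffectBlock(
            coh_Z, bas.rw2_structure(lex.K), (1.0, 0.005),
            np.vstack([eng.sum_to_zero_constraint(lex.K),
                       eng.linear_trend_constraint(lex.K)]), "cohort"),
        eng.RandomEffectBlock(np.eye(n), bas.iid_structure(n), (1.0, 0.005),
                              None, "overdispersion"),
    ]
    return eng.LatentGaussianProblem(
        y=y, offset=np.log(N.reshape(-1)), X=np.ones((n, 1)), blocks=blocks,
        family="poisson")


class TestOracles:
    def test_gaussian_likelihood_matches_gls_closed_form(self, rng):
        n, p = 30, 3
        X = rng.standard_normal((n, p))
        beta_true = np.array([1.0, -0.5, 2.0])
        kappa = 4.0  # known noise precision
        offset = rng.standard_normal(n)
        y = offset + X @ beta_true + rng.standard_normal(n) / np.sqrt(kappa)
        prior_prec = 0.5
        prob = eng.LatentGaussianProblem(
            y=y, offset=offset, X=X, blocks=[], family="gaussian",
            fixed_prec=prior_prec, gaussian_noise_prec=kappa)
        pa = eng.fit_latent_gaussian(prob, seed=0, n_draws=500)
        # conjugate posterior: N((kX'X + k0 I)^-1 kX'(y-off), (kX'X+k0I)^-1)
        A = kappa * X.T @ X + prior_prec * np.eye(p)
        mean = np.linalg.solve(A, kappa * X.T @ (y - offset))
        eta_mean, eta_sd = pa.eta_summary()
        np.testing.assert_allclose(eta_mean, offset + X @ mean, atol=1e-6)
        cov = np.linalg.inv(A)
        sd = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
        np.testing.assert_allclose(eta_sd, sd, atol=1e-6)

    def test_poisson_flat_prior_mode_is_overall_rate(self, rng):
        N = np.full(25, 1e4)
        y = rng.poisson(3e-4 * N).astype(float)
        prob = eng.LatentGaussianProblem(
            y=y, offset=np.log(N), X=np.ones((25, 1)), family="poisson",
            fixed_prec=1e-10)
        pa = eng.fit_latent_gaussian(prob, seed=0, n_draws=500)
        red = pa._reduced
        u_mode, *_ = red.newton_mode(pa.theta_mode)
        assert np.exp(u_mode[0]) == pytest.approx(y.sum() / N.sum(), rel=1e-6)

    def test_two_seeds_agree_on_eta_within_mc_error(self):
        prob = bapc_fixture_problem()
        pa1 = eng.fit_latent_gaussian(prob, seed=1, n_draws=1000,
                                      n_theta_points=101)
        pa2 = eng.fit_latent_gaussian(prob, seed=2, n_draws=1000,
                                      n_theta_points=101)
        m1, s1 = pa1.eta_summary()
        m2, s2 = pa2.eta_summary()
        assert np.max(np.abs(m1 - m2) / s1) < 0.15

    def test_constraints_hold_exactly_in_draws(self):
        prob = bapc_fixture_problem()
        for method, kw in [("laplace", {"n_draws": 300}),
                           ("mcmc", {"mcmc_iter": 400, "mcmc_burn": 100})]:
            pa = eng.fit_latent_gaussian(prob, seed=3, method=method, **kw)
            assert pa.constraint_residual() < 1e-8


class TestPredictive:
    def _degenerate_posterior(self, eta0=-6.0, n_cells=400):
        """All posterior mass at one eta: predictive draws are pure noise."""
        prob = eng.LatentGaussianProblem(
            y=np.ones(n_cells), offset=np.zeros(n_cells),
            X=np.ones((n_cells, 1)), family="poisson")
        pa = eng.fit_latent_gaussian(prob, seed=0, n_draws=200)
        pa.u_draws = np.full((200, 1), eta0)
        return pa

    def test_degenerate_posterior_gives_poisson_moments(self):
        pa = self._degenerate_posterior()
        N = 2e5
        rows = np.ones((400, 1))
        draws = eng.posterior_predictive(pa, rows, np.full(400, np.log(N)),
                                         n_samples=300, seed=1)
        lam = N * np.exp(-6.0)
        assert draws.mean() == pytest.approx(lam, rel=0.02)
        assert draws.var() == pytest.approx(lam, rel=0.1)

    def test_doubling_offset_doubles_predictive_mean(self):
        pa = self._degenerate_posterior()
        rows = np.ones((50, 1))
        d1 = eng.posterior_predictive(pa, rows, np.full(50, np.log(1e5)),
                                      n_samples=2000, seed=2)
        d2 = eng.posterior_predictive(pa, rows, np.full(50, np.log(2e5)),
                                      n_samples=2000, seed=2)
        assert d2.mean() / d1.mean() == pytest.approx(2.0, rel=0.05)

    def test_nb_with_huge_size_matches_poisson_distribution(self, rng):
        N = np.full(60, 5e4)
        y = rng.poisson(4e-4 * N).astype(float)
        prob = eng.LatentGaussianProblem(
            y=y, offset=np.log(N), X=np.ones((60, 1)),
            family="negative_binomial")
        pa = eng.fit_latent_gaussian(prob, seed=4, n_draws=400)
        pa.u_draws[:] = pa.u_draws.mean()
        pa.theta_draws[:] = np.log(1e8)  # force the Poisson limit
        rows = np.ones((1, 1))
        nb = eng.posterior_predictive(pa, rows, [np.log(5e4)],
                                      n_samples=4000, seed=5).ravel()
        lam = 5e4 * np.exp(pa.u_draws[0, 0])
        pois = stats.poisson.rvs(lam, size=4000,
                                 random_state=np.random.RandomState(6))
        assert stats.ks_2samp(nb, pois).pvalue > 0.01

    def test_too_few_samples_rejected(self):
        pa = self._degenerate_posterior()
        with pytest.raises(ValueError, match="100"):
            eng.posterior_predictive(pa, np.ones((1, 1)), [0.0], n_samples=50)


def test_dependent_constraint_rows_rejected():
    Z = np.ones((4, 3))
    con = np.vstack([np.ones(3), 2 * np.ones(3)])
    with pytest.raises(ValueError, match="constraint"):
        eng.LatentGaussianProblem(
            y=np.ones(4), offset=np.zeros(4), X=np.ones((4, 1)),
            blocks=[eng.RandomEffectBlock(Z, bas.iid_structure(3),
                                          (1.0, 0.005), con)],
            family="poisson")


def test_nonconvergence_is_flagged_not_silent():
    prob = bapc_fixture_problem(I=3, J=4)
    pa = eng.fit_latent_gaussian(prob, seed=0, maxfev=3, n_draws=200)
    assert "converged" in pa.diagnostics  # always reported, True or False
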