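"""Approximate Bayesian inference for latent Gaussian count models.

The models fitted here share one structure: counts ``y`` with a Poisson
or negative-binomial likelihood, a log link with a fixed offset
``log N``, and a linear predictor ``eta = X beta + sum_r Z_r z_r`` where
each random-effect vector ``z_r`` carries an intrinsic Gaussian prior
``z_r ~ N(0, (tau_r Q_r)^-)`` with a Gamma prior on the precision
``tau_r``.  Linear constraints (sum-to-zero and similar) remove the
structure matrices' null spaces.

Two inference routes are provided behind one interface:

``laplace`` (default)
    A nested-Laplace scheme: for fixed hyperparameters the latent field
    is approximated by the Gaussian centred at the conditional mode with
    the negative Hessian as precision; the hyperparameter posterior is
    the Laplace marginal, explored by numerical optimisation and a
    Gaussian approximation on the log-precision scale.  Posterior draws
    mix over hyperparameter samples.

``mcmc``
    A one-block Markov chain Monte Carlo sampler: conjugate Gamma
    updates for the precisions, and a joint Metropolis-Hastings update
    of the whole latent field using the Gaussian Taylor expansion of the
    target at the current state as proposal.  Slower but asymptotically
    exact; it serves as the gold standard the Laplace route is checked
    against.

Constraints are enforced exactly by reparametrising each block onto an
orthonormal basis of the constraint null space, so every draw satisfies
them to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, null_space, solve_triangular
from scipy.special import gammaln

from .basis import StructureMatrix

__all__ = [
    "RandomEffectBlock",
    "LatentGaussianProblem",
    "PosteriorApproximation",
    "fit_latent_gaussian",
    "posterior_predictive",
    "sum_to_zero_constraint",
    "linear_trend_constraint",
]

_EIG_TOL = 1e-8


def sum_to_zero_constraint(q: int) -> np.ndarray:
    """Single constraint row forcing the block to sum to zero."""
    return np.ones((1, q))


def linear_trend_constraint(q: int) -> np.ndarray:
    """Constraint row removing the (centred) linear component."""
    x = np.arange(q, dtype=float)
    return (x - x.mean())[None, :]


@dataclass
class RandomEffectBlock:
    """One structured random effect ``Z z`` with prior ``z ~ N(0, (tau Q)^-)``."""

    design: np.ndarray  # (n, q)
    structure: StructureMatrix
    prior: tuple[float, float] = (1.0, 0.005)  # Gamma(shape a, rate b) on tau
    constraints: np.ndarray | None = None  # (c, q), rows A with A z = 0
    name: str = "z"

    @property
    def q(self) -> int:
        return self.design.shape[1]


@dataclass
class LatentGaussianProblem:
    """Data, designs and priors for one latent Gaussian count model."""

    y: np.ndarray
    offset: np.ndarray  # log person-years, added to the linear predictor
    X: np.ndarray  # fixed-effect design (n, p); may have 0 columns
    blocks: list[RandomEffectBlock] = field(default_factory=list)
    family: str = "poisson"  # poisson | negative_binomial | gaussian
    fixed_prec: float = 1e-6  # vague Gaussian prior precision on beta
    nb_size_prior: tuple[float, float] = (1.0, 0.01)  # Gamma on NB size
    gaussian_noise_prec: float = 1.0  # known, gaussian family only

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.offset = np.asarray(self.offset, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.size
        if self.offset.size != n or self.X.shape[0] != n:
            raise ValueError("y, offset and X must share their row count")
        for b in self.blocks:
            if b.design.shape[0] != n:
                raise ValueError(f"block {b.name!r} design rows != len(y)")
            if b.constraints is not None:
                c = np.atleast_2d(b.constraints)
                if np.linalg.matrix_rank(c) < c.shape[0]:
                    raise ValueError(f"block {b.name!r}: dependent constraint rows")
        if self.family not in ("poisson", "negative_binomial", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")


# ---------------------------------------------------------------------
# internal reduced representation
# ---------------------------------------------------------------------


class _Reduced:
    """Problem reparametrised so constraints hold by construction.

    Each block's coefficient vector is written ``z_r = T_r v_r`` with
    ``T_r`` an orthonormal basis of the constraint null space; the
    working latent vector is ``u = (beta, v_1, ..., v_R)``.
    """

    def __init__(self, p: LatentGaussianProblem):
        self.p = p
        self.n = p.y.size
        self.np_fixed = p.X.shape[1]
        designs = [p.X] if self.np_fixed else []
        self.T: list[np.ndarray] = []
        self.Qr: list[np.ndarray] = []
        self.rank: list[int] = []
        self.loggdet_base: list[float] = []
        self.slices: list[slice] = []
        pos = self.np_fixed
        for b in p.blocks:
            if b.constraints is None:
                T = np.eye(b.q)
            else:
                T = null_space(np.atleast_2d(b.constraints))
            Qr = T.T @ b.structure.Q @ T
            w = np.linalg.eigvalsh(Qr)
            keep = w > _EIG_TOL * max(1.0, w.max() if w.size else 1.0)
            self.T.append(T)
            self.Qr.append(Qr)
            self.rank.append(int(keep.sum()))
            self.loggdet_base.append(float(np.log(w[keep]).sum()))
            designs.append(b.design @ T)
            self.slices.append(slice(pos, pos + T.shape[1]))
            pos += T.shape[1]
        self.m = pos
        self.U = np.hstack(designs) if designs else np.zeros((self.n, 0))
        self.n_tau = len(p.blocks)
        self.n_theta = self.n_tau + (1 if p.family == "negative_binomial" else 0)

    # -- likelihood ---------------------------------------------------

    def loglik(self, eta: np.ndarray, theta: np.ndarray):
        """Per-cell log-likelihood and its first two eta-derivatives."""
        y, fam = self.p.y, self.p.family
        if fam == "gaussian":
            k = self.p.gaussian_noise_prec
            r = y - eta
            return -0.5 * k * r * r, k * r, np.full_like(eta, -k)
        eta = np.clip(eta, -40.0, 40.0)  # |log mu| > 40 is numerically absurd
        mu = np.exp(eta)
        if fam == "poisson":
            ll = y * eta - mu - gammaln(y + 1)
            return ll, y - mu, -mu
        s = math.exp(min(max(theta[-1], -30.0), 30.0))  # NB size; var = mu + mu^2/s
        ll = (gammaln(y + s) - gammaln(s) - gammaln(y + 1)
              + s * math.log(s) + y * eta - (y + s) * np.log(s + mu))
        d1 = y - (y + s) * mu / (s + mu)
        d2 = -(y + s) * s * mu / (s + mu) ** 2
        return ll, d1, d2

    def loglik_d3(self, eta: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Third eta-derivative of the log-likelihood (skewness term)."""
        y, fam = self.p.y, self.p.family
        if fam == "gaussian":
            return np.zeros_like(eta)
        eta = np.clip(eta, -40.0, 40.0)
        mu = np.exp(eta)
        if fam == "poisson":
            return -mu
        s = math.exp(min(max(theta[-1], -30.0), 30.0))
        return -(y + s) * s * mu * (s - mu) / (s + mu) ** 3

    def skew_shift(self, u_star: np.ndarray, theta: np.ndarray, cf):
        """First-order posterior-mean correction to the Gaussian centre.

        The Gaussian approximation sits at the conditional mode; the
        true conditional mean is shifted by the likelihood's skewness:
        delta = 0.5 * H^-1 U' (l''' * Var[eta]) with Var[eta] the
        Gaussian approximation's per-cell variance.  Returns the shift
        in u-space together with Var[eta] per cell.
        """
        eta = self.p.offset + self.U @ u_star
        d3 = self.loglik_d3(eta, theta)
        V = cho_solve(cf, self.U.T)  # (m, n) = H^-1 U'
        var_eta = np.einsum("cm,mc->c", self.U, V)
        return 0.5 * (V @ (d3 * var_eta)), var_eta

    def prior_quad(self, theta: np.ndarray) -> np.ndarray:
        """Block-diagonal prior precision of u for given log-precisions."""
        Qp = np.zeros((self.m, self.m))
        if self.np_fixed:
            Qp[: self.np_fixed, : self.np_fixed] = (
                self.p.fixed_prec * np.eye(self.np_fixed)
            )
        for r, sl in enumerate(self.slices):
            Qp[sl, sl] = math.exp(theta[r]) * self.Qr[r]
        return Qp

    def prior_loggdet(self, theta: np.ndarray) -> float:
        """Generalized log-determinant of the latent prior precision."""
        out = self.np_fixed * math.log(self.p.fixed_prec)
        for r in range(self.n_tau):
            out += self.rank[r] * theta[r] + self.loggdet_base[r]
        return out

    def log_hyperprior(self, theta: np.ndarray) -> float:
        """Gamma priors on precisions (and NB size), on the log scale."""
        out = 0.0
        for r, b in enumerate(self.p.blocks):
            a, rate = b.prior
            out += a * theta[r] - rate * math.exp(theta[r])
        if self.p.family == "negative_binomial":
            a, rate = self.p.nb_size_prior
            out += a * theta[-1] - rate * math.exp(theta[-1])
        return out

    # -- inner Gaussian approximation ---------------------------------

    def newton_mode(self, theta: np.ndarray, u0: np.ndarray | None = None,
                    max_iter: int = 50, tol: float = 1e-9):
        """Conditional posterior mode of u given theta, by damped Newton."""
        Qp = self.prior_quad(theta)
        u = np.zeros(self.m) if u0 is None else u0.copy()
        eta = self.p.offset + self.U @ u
        ll, d1, d2 = self.loglik(eta, theta)
        f = ll.sum() - 0.5 * u @ Qp @ u
        cf = None
        for _ in range(max_iter):
            W = np.maximum(-d2, 1e-10)
            H = Qp + (self.U * W[:, None]).T @ self.U
            g = self.U.T @ d1 - Qp @ u
            try:
                cf = cho_factor(H, lower=True)
            except np.linalg.LinAlgError:
                H = H + 1e-8 * np.eye(self.m)
                cf = cho_factor(H, lower=True)
            step = cho_solve(cf, g)
            t = 1.0
            for _ in range(30):
                u_new = u + t * step
                eta = self.p.offset + self.U @ u_new
                ll, d1n, d2n = self.loglik(eta, theta)
                f_new = ll.sum() - 0.5 * u_new @ Qp @ u_new
                if np.isfinite(f_new) and f_new >= f - 1e-12:
                    break
                t /= 2
            gain = f_new - f
            u, f, d1, d2 = u_new, f_new, d1n, d2n
            if abs(gain) < tol * (1 + abs(f)):
                break
        W = np.maximum(-d2, 1e-10)
        H = Qp + (self.U * W[:, None]).T @ self.U
        try:
            cf = cho_factor(H, lower=True)
        except np.linalg.LinAlgError:
            cf = cho_factor(H + 1e-8 * np.eye(self.m), lower=True)
        return u, f, H, cf, Qp

    def log_marginal(self, theta: np.ndarray, u0=None):
        """Laplace approximation to log p(y | theta) + log p(theta)."""
        u, f, H, cf, _ = self.newton_mode(theta, u0)
        logdet_H = 2.0 * np.log(np.diag(cf[0])).sum()
        lm = f + 0.5 * self.prior_loggdet(theta) - 0.5 * logdet_H
        return lm + self.log_hyperprior(theta), u

    def expand(self, u: np.ndarray) -> np.ndarray:
        """Map reduced coordinates back to (beta, z_1, ..., z_R)."""
        parts = [u[..., : self.np_fixed]]
        for T, sl in zip(self.T, self.slices):
            parts.append(u[..., sl] @ T.T)
        return np.concatenate(parts, axis=-1)


# ---------------------------------------------------------------------
# posterior object
# ---------------------------------------------------------------------


@dataclass
class PosteriorApproximation:
    """Posterior draws and summaries for one latent Gaussian fit.

    Draws are stored in the *full* coordinate system
    ``(beta, z_1, ..., z_R)``; linear constraints hold exactly.
    """

    method: str
    problem: LatentGaussianProblem
    u_draws: np.ndarray  # (S, p + sum q_r)
    theta_draws: np.ndarray  # (S, n_theta)
    theta_mode: np.ndarray
    diagnostics: dict
    _reduced: _Reduced
    # analytic training-grid eta summaries (laplace route); draw-based otherwise
    eta_mean_: np.ndarray | None = None
    eta_sd_: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.u_draws.shape[0]

    def block_slice(self, name: str) -> slice:
        pos = self.problem.X.shape[1]
        for b in self.problem.blocks:
            if b.name == name:
                return slice(pos, pos + b.q)
            pos += b.q
        raise KeyError(name)

    def fixed_slice(self) -> slice:
        return slice(0, self.problem.X.shape[1])

    def linpred_draws(self) -> np.ndarray:
        """Draws of eta (offset included) at the training cells."""
        full_design = self._full_design()
        return self.problem.offset + self.u_draws @ full_design.T

    def _full_design(self) -> np.ndarray:
        cols = [self.problem.X] if self.problem.X.shape[1] else []
        cols += [b.design for b in self.problem.blocks]
        return np.hstack(cols)

    def eta_summary(self) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and SD of eta (offset included) per training cell.

        The laplace route reports the Gaussian-mixture moments exactly
        (no draw noise); the mcmc route summarises its stored draws.
        """
        if self.eta_mean_ is not None:
            return self.eta_mean_, self.eta_sd_
        d = self.linpred_draws()
        return d.mean(axis=0), d.std(axis=0, ddof=1)

    def constraint_residual(self) -> float:
        """Largest |A z| over draws and constraints; ~1e-12 by construction."""
        worst = 0.0
        pos = self.problem.X.shape[1]
        for b in self.problem.blocks:
            if b.constraints is not None:
                res = self.u_draws[:, pos: pos + b.q] @ np.atleast_2d(b.constraints).T
                scale = max(1.0, float(np.abs(self.u_draws[:, pos: pos + b.q]).max()))
                worst = max(worst, float(np.abs(res).max()) / scale)
            pos += b.q
        return worst


# ---------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------


def _theta_init(red: _Reduced) -> np.ndarray:
    """Data-scale starting point for the log-precisions.

    Each block's initial precision is chosen so that the prior spread of
    its contribution to eta matches the empirical spread of the log
    rates: tau_0 = mean(||Z_i||^2) / var(log rate).  Starting in a
    strong-shrinkage basin instead (e.g. at the prior mean precision)
    can trap the hyperparameter search at a collapsed mode where smooth
    terms are flattened away and overdispersion absorbs the signal.
    """
    p = red.p
    if p.family == "gaussian":
        v = float(np.var(p.y))
    else:
        v = float(np.var(np.log(p.y + 0.5) - p.offset))
    v = max(v, 0.1)
    th = []
    pos = red.np_fixed
    for T in red.T:
        q = T.shape[1]
        Zr = red.U[:, pos: pos + q]
        row_sq = float(np.mean(np.sum(Zr * Zr, axis=1)))
        tau0 = max(row_sq, 1e-8) / v
        th.append(min(max(math.log(tau0), -10.0), 5.0))
        pos += q
    if p.family == "negative_binomial":
        th.append(math.log(10.0))
    return np.asarray(th)


def _fit_laplace(red: _Reduced, seed: int, n_draws: int, n_theta_points: int,
                 maxfev: int | None) -> PosteriorApproximation:
    rng = np.random.default_rng(seed)
    diagnostics: dict = {"converged": True}
    th0 = _theta_init(red)

    if red.n_theta == 0:
        u_star, _, _, cf, _ = red.newton_mode(th0)
        shift, var_eta = red.skew_shift(u_star, th0, cf)
        centre = u_star + shift
        z = rng.standard_normal((n_draws, red.m))
        draws = centre + solve_triangular(cf[0], z.T, lower=True, trans="T").T
        return PosteriorApproximation(
            "laplace", red.p, red.expand(draws), np.zeros((n_draws, 0)),
            th0, diagnostics, red,
            eta_mean_=red.p.offset + red.U @ centre,
            eta_sd_=np.sqrt(var_eta))

    # hyperparameter mode
    warm = {"u": None}

    def neg(th):
        val, u = red.log_marginal(th, warm["u"])
        warm["u"] = u
        return -val

    d0 = red.n_theta
    simplex = np.vstack([th0, th0 + 1.5 * np.eye(d0)])
    opts = {"xatol": 5e-3, "fatol": 5e-3, "initial_simplex": simplex}
    if maxfev is not None:
        opts["maxfev"] = maxfev
    res = optimize.minimize(neg, th0, method="Nelder-Mead", options=opts)
    theta_hat = res.x
    diagnostics["theta_opt_nfev"] = int(res.nfev)
    diagnostics["converged"] = bool(res.success or res.fun < neg(th0))

    # Gaussian approximation over theta via finite-difference Hessian
    d = red.n_theta
    h = 0.1
    f0 = -neg(theta_hat)
    Hth = np.zeros((d, d))
    fp = np.zeros(d)
    fm = np.zeros(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = h
        fp[i] = -neg(theta_hat + e)
        fm[i] = -neg(theta_hat - e)
        Hth[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            fpp = -neg(theta_hat + ei + ej)
            Hth[i, j] = Hth[j, i] = (
                fpp - fp[i] - fp[j] + f0
            ) / h**2
    prec = -Hth
    try:
        w, V = np.linalg.eigh(prec)
        # floor the precision: caps hyperparameter spread at sd 2 per
        # direction, guarding against flat/noisy finite differences
        w = np.maximum(w, 0.25)
        cov_theta = (V / w) @ V.T
    except np.linalg.LinAlgError:
        cov_theta = 0.25 * np.eye(d)
    diagnostics["theta_cov_diag"] = np.diag(cov_theta).tolist()

    # mix posterior draws over theta samples; antithetic pairs cancel the
    # first-order dependence of the conditional mean on theta
    Lth = np.linalg.cholesky(cov_theta + 1e-10 * np.eye(d))
    n_pts = max(1, n_theta_points)
    half = (n_pts - 1 + 1) // 2
    dev = rng.standard_normal((half, d)) @ Lth.T
    theta_pts = np.vstack([np.zeros((1, d)), dev, -dev])[:n_pts] + theta_hat
    # importance weights: true Laplace marginal over the Gaussian proposal,
    # correcting the skew of the hyperparameter posterior
    prec_prop = np.linalg.inv(cov_theta)
    sign, logdet_prop = np.linalg.slogdet(prec_prop)
    centres = np.empty((n_pts, red.m))
    cfs = []
    var_etas = np.empty((n_pts, red.n))
    log_w = np.empty(n_pts)
    u_warm = warm["u"]
    for t_idx, tp in enumerate(theta_pts):
        u_star, f_val, _, cf, _ = red.newton_mode(tp, u_warm)
        u_warm = u_star
        logdet_H = 2.0 * np.log(np.diag(cf[0])).sum()
        lm = (f_val + 0.5 * red.prior_loggdet(tp) - 0.5 * logdet_H
              + red.log_hyperprior(tp))
        dev = tp - theta_hat
        logq = 0.5 * logdet_prop - 0.5 * dev @ prec_prop @ dev
        log_w[t_idx] = lm - logq
        shift, var_eta = red.skew_shift(u_star, tp, cf)
        centres[t_idx] = u_star + shift
        var_etas[t_idx] = var_eta
        cfs.append(cf)
    log_w -= log_w.max()
    w = np.exp(log_w)
    w /= w.sum()
    diagnostics["theta_is_ess"] = float(1.0 / np.sum(w**2))

    # analytic mixture moments of eta, importance-weighted
    eta_centres = red.p.offset + centres @ red.U.T
    eta_mean = w @ eta_centres
    eta_var = np.maximum(w @ (var_etas + eta_centres**2) - eta_mean**2, 0.0)

    # allocate stored draws proportionally to the weights
    per = np.floor(w * n_draws).astype(int)
    short = n_draws - per.sum()
    if short > 0:
        order = np.argsort(-(w * n_draws - per))
        per[order[:short]] += 1
    u_draws = np.empty((n_draws, red.m))
    theta_draws = np.empty((n_draws, d))
    pos = 0
    for t_idx, k in enumerate(per):
        if k == 0:
            continue
        z = rng.standard_normal((k, red.m))
        # H = L L'; draws = centre + L^{-T} z
        u_draws[pos: pos + k] = centres[t_idx] + solve_triangular(
            cfs[t_idx][0], z.T, lower=True, trans="T").T
        theta_draws[pos: pos + k] = theta_pts[t_idx]
        pos += k
    return PosteriorApproximation(
        "laplace", red.p, red.expand(u_draws), theta_draws,
        theta_hat, diagnostics, red,
        eta_mean_=eta_mean, eta_sd_=np.sqrt(eta_var))


def _fit_mcmc(red: _Reduced, seed: int, n_iter: int, burn: int,
              thin: int) -> PosteriorApproximation:
    rng = np.random.default_rng(seed)
    p = red.p
    theta = _theta_init(red)
    u, *_ = red.newton_mode(theta)

    def taylor_proposal(u_cur, Qp, theta):
        """Gaussian expansion of the target around u_cur: mean + chol."""
        eta = p.offset + red.U @ u_cur
        ll, d1, d2 = red.loglik(eta, theta)
        W = -d2
        H = Qp + (red.U * W[:, None]).T @ red.U
        g = red.U.T @ d1 - Qp @ u_cur
        cf = cho_factor(H, lower=True)
        mean = u_cur + cho_solve(cf, g)
        return mean, cf, ll.sum() - 0.5 * u_cur @ Qp @ u_cur

    def q_logpdf(x, mean, cf):
        # N(mean, H^-1) with H = L L': 0.5 log|H| - 0.5 ||L'(x-mean)||^2
        # (cho_factor leaves junk in the unused triangle; mask it)
        L = np.tril(cf[0])
        w = L.T @ (x - mean)
        return np.log(np.diag(L)).sum() - 0.5 * w @ w

    keep_u, keep_th = [], []
    n_acc = 0
    n_prop = 0
    nb = p.family == "negative_binomial"
    for it in range(n_iter):
        # 1. conjugate Gamma updates for the block precisions
        for r, b in enumerate(p.blocks):
            v = u[red.slices[r]]
            quad = float(v @ red.Qr[r] @ v)
            a, rate = b.prior
            theta[r] = math.log(rng.gamma(a + 0.5 * red.rank[r],
                                          1.0 / (rate + 0.5 * quad)))
        # 2. random-walk Metropolis on log NB size
        if nb:
            eta = p.offset + red.U @ u
            ll0 = red.loglik(eta, theta)[0].sum() + red.log_hyperprior(theta)
            prop = theta.copy()
            prop[-1] = theta[-1] + 0.4 * rng.standard_normal()
            ll1 = red.loglik(eta, prop)[0].sum() + red.log_hyperprior(prop)
            if math.log(rng.uniform()) < ll1 - ll0:
                theta = prop
        # 3. one-block MH on the latent field with Taylor proposal
        Qp = red.prior_quad(theta)
        mean_f, cf_f, f_cur = taylor_proposal(u, Qp, theta)
        z = rng.standard_normal(red.m)
        u_prop = mean_f + solve_triangular(cf_f[0], z, lower=True, trans="T")
        eta_p = p.offset + red.U @ u_prop
        ll_p = red.loglik(eta_p, theta)[0].sum()
        f_prop = ll_p - 0.5 * u_prop @ Qp @ u_prop
        mean_b, cf_b, _ = taylor_proposal(u_prop, Qp, theta)
        log_alpha = (f_prop - f_cur
                     + q_logpdf(u, mean_b, cf_b)
                     - q_logpdf(u_prop, mean_f, cf_f))
        n_prop += 1
        if math.log(rng.uniform()) < log_alpha:
            u = u_prop
            n_acc += 1
        if it >= burn and (it - burn) % thin == 0:
            keep_u.append(u.copy())
            keep_th.append(theta.copy())
    u_draws = np.asarray(keep_u)
    theta_draws = np.asarray(keep_th)
    diagnostics = {
        "converged": True,
        "acceptance_rate": n_acc / max(n_prop, 1),
        "n_kept": len(keep_u),
    }
    if diagnostics["acceptance_rate"] < 0.1:
        diagnostics["converged"] = False
    return PosteriorApproximation(
        "mcmc", p, red.expand(u_draws), theta_draws,
        theta_draws.mean(axis=0) if len(theta_draws) else np.zeros(red.n_theta),
        diagnostics, red)


def fit_latent_gaussian(
    problem: LatentGaussianProblem,
    seed: int = 0,
    method: str = "laplace",
    n_draws: int = 2000,
    n_theta_points: int = 25,
    mcmc_iter: int = 3000,
    mcmc_burn: int = 500,
    mcmc_thin: int = 1,
    maxfev: int | None = None,
) -> PosteriorApproximation:
    """Fit a latent Gaussian count model and return posterior draws.

    Parameters
    ----------
    problem : LatentGaussianProblem
        Data, designs, structures and priors.
    seed : int
        Seed for every random element of the approximation.
    method : {"laplace", "mcmc"}
        Inference route; see the module docstring.
    n_draws : int
        Number of posterior draws to store (laplace route).
    n_theta_points : int
        Number of hyperparameter samples the laplace draws mix over.
    mcmc_iter, mcmc_burn, mcmc_thin : int
        Chain length controls for the mcmc route.
    maxfev : int, optional
        Cap on hyperparameter-objective evaluations (budget control).
    """
    red = _Reduced(problem)
    if method == "laplace":
        return _fit_laplace(red, seed, n_draws, n_theta_points, maxfev)
    if method == "mcmc":
        return _fit_mcmc(red, seed, mcmc_iter, mcmc_burn, mcmc_thin)
    raise ValueError(f"unknown method {method!r}")


def posterior_predictive(
    pa: PosteriorApproximation,
    design_rows: np.ndarray,
    offsets: np.ndarray,
    n_samples: int = 1000,
    seed: int = 0,
    observation_noise: bool = True,
) -> np.ndarray:
    """Draw predictive counts at new cells given full-coordinate design rows.

    Each returned draw integrates hyperparameter uncertainty (through the
    stored joint draws), latent-field uncertainty and — unless
    ``observation_noise=False`` — observation noise; without it the
    draws are of the expected count ``N * exp(eta)`` itself.  Rows must
    be expressed in the full coordinate system ``(beta, z_1, ..., z_R)``;
    effects that need extrapolation beyond the training grid
    (random-walk extensions) are the model layer's job.
    """
    if n_samples < 100:
        raise ValueError("need at least 100 samples for interval construction")
    rng = np.random.default_rng(seed)
    design_rows = np.atleast_2d(design_rows)
    offsets = np.asarray(offsets, dtype=float).ravel()
    idx = rng.integers(0, pa.n_draws, size=n_samples)
    eta = offsets + pa.u_draws[idx] @ design_rows.T
    fam = pa.problem.family
    if fam == "gaussian":
        if not observation_noise:
            return eta
        sd = pa.problem.gaussian_noise_prec ** -0.5
        return eta + sd * rng.standard_normal(eta.shape)
    mu = np.exp(np.clip(eta, -40.0, 40.0))
    if not observation_noise:
        return mu
    if fam == "poisson":
        return rng.poisson(mu).astype(float)
    if fam == "negative_binomial":
        size = np.exp(pa.theta_draws[idx, -1])[:, None]
        # NB(mean mu, size s) as Gamma-Poisson mixture
        lam = rng.gamma(np.broadcast_to(size, mu.shape), mu / size)
        return rng.poisson(lam).astype(float)
    raise ValueError(fam)
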