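"""Parallel-tempered MCMC for adaptive gradient matching.

A ladder of M power posteriors p_i ∝ prior * likelihood^alpha_i is run in
parallel, with alpha_1 = 0 (the prior) up to alpha_M = 1 (the posterior);
the alphas are M equally spaced values on [0, 1] raised to the power 5, so
the ladder concentrates rungs near the prior.  Each rung i is paired with a
fixed gradient-mismatch variance gamma_i, largest at the prior end and
decreasing geometrically (log-base-2 or log-base-10 increments starting at
1) towards ~0 at the posterior rung: cold chains force the interpolant
slopes to agree with the ODE, hot chains let them decouple.  The INF
variant instead samples a single gamma per rung from its prior-posterior.

Within each sweep every chain performs Metropolis-Hastings updates of
theta (random walk on a log scale for positivity-constrained parameters,
plus an occasional independence proposal from the prior), of the GP
hyperparameters eta jointly with the latent states through the whitening
x_s = phi_s + L_s u_s (L_s a Cholesky factor of K_{eta_s}), of the whitened
latents u_s via preconditioned Crank-Nicolson, and optionally of sigma^2
and gamma.  One swap between a uniformly chosen pair of chains is proposed
per sweep, exchanging the full state (theta, X, eta, sigma^2) while each
rung keeps its own (alpha, gamma).

What is tempered: the data likelihood and the gradient-mismatch factor are
raised to alpha; the GP prior on the latent states and all parameter priors
are untempered, so every rung is a proper distribution and the alpha = 0
rung reproduces the priors exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg

from .agm_posterior import LOG2PI, PriorSet, default_priors
from .gp_interpolation import (GPFitResult, KernelSpec, chol_with_jitter,
                               gp_fit_ml, kernel_derivative_blocks, kernel_eval)
from .ode_models import ODEModel
from .synthetic_data import Dataset

MODES = ("lb2", "lb10", "inf")


def make_alpha_ladder(M: int) -> np.ndarray:
    """Power-posterior temperatures ((i-1)/(M-1))^5 for i = 1..M."""
    if M < 2:
        raise ValueError("need at least 2 chains")
    return (np.arange(M) / (M - 1)) ** 5


def make_gamma_ladder(M: int, base: int, start: float = 1.0) -> np.ndarray:
    """Mismatch variances start * base^-(i-1); chain i at alpha_i gets gamma_i."""
    if M < 2:
        raise ValueError("need at least 2 chains")
    if base not in (2, 10):
        raise ValueError("ladder base must be 2 or 10")
    return start * float(base) ** -np.arange(M)


# ---------------------------------------------------------------------------

def _to_z(theta: np.ndarray, positive: Sequence[bool]) -> np.ndarray:
    z = np.array(theta, dtype=float)
    for k, pos in enumerate(positive):
        if pos:
            z[k] = math.log(max(theta[k], 1e-300))
    return z


def _to_theta(z: np.ndarray, positive: Sequence[bool]) -> np.ndarray:
    th = np.array(z, dtype=float)
    for k, pos in enumerate(positive):
        if pos:
            th[k] = math.exp(min(z[k], 300.0))
    return th


def _log_jac(z: np.ndarray, positive: Sequence[bool]) -> float:
    # |d theta / d z| = prod over positive params of exp(z)
    return float(sum(z[k] for k, pos in enumerate(positive) if pos))


class _SpeciesCache:
    """Per-species geometry derived from (eta_s, gamma): factors and inverses."""

    __slots__ = ("spec", "L", "M", "A", "Binv", "logdetK", "logdetB")

    def __init__(self, spec: KernelSpec, t: np.ndarray, gamma: float):
        self.spec = spec
        blocks = kernel_derivative_blocks(spec, t)
        self.L = chol_with_jitter(blocks.K)
        # conditional of xdot given x: mu = cov(xdot,x) K^{-1} (x - phi);
        # cov(xdot,x) is the d/dt_i block Kp, and pK = Kp^T, so with
        # W = L^{-1} pK we get mu = W^T u and A = K'' - W^T W
        W = linalg.solve_triangular(self.L, blocks.pK, lower=True,
                                    check_finite=False)
        self.M = W.T                       # mu_s = M @ u_s
        A = blocks.Kpp - W.T @ W
        self.A = 0.5 * (A + A.T)
        self.logdetK = 2.0 * float(np.log(np.diag(self.L)).sum())
        self.set_gamma(gamma)

    def set_gamma(self, gamma: float) -> None:
        Lb = chol_with_jitter(self.A + gamma * np.eye(self.A.shape[0]),
                              what="A + gamma*I")
        self.logdetB = 2.0 * float(np.log(np.diag(Lb)).sum())
        Linv = linalg.solve_triangular(Lb, np.eye(Lb.shape[0]), lower=True,
                                       check_finite=False)
        self.Binv = Linv.T @ Linv

    def mismatch_quad_parts(self, gamma: float) -> tuple[np.ndarray, float]:
        """(Binv, logdetB) under a different gamma, without mutating the cache."""
        Lb = chol_with_jitter(self.A + gamma * np.eye(self.A.shape[0]),
                              what="A + gamma*I")
        Linv = linalg.solve_triangular(Lb, np.eye(Lb.shape[0]), lower=True,
                                       check_finite=False)
        return Linv.T @ Linv, 2.0 * float(np.log(np.diag(Lb)).sum())


class Chain:
    """One tempering rung: parameters, whitened latents and cached terms."""

    def __init__(self, alpha: float, gamma: float, model: ODEModel,
                 priors: PriorSet, t: np.ndarray, Y: np.ndarray,
                 phi: np.ndarray, theta0: np.ndarray,
                 eta0: Sequence[KernelSpec], sigma2: np.ndarray,
                 u0: np.ndarray, sample_sigma: bool, sample_gamma: bool):
        self.alpha = alpha
        self.gamma = gamma
        self.model = model
        self.priors = priors
        self.t = t
        self.Y = Y
        self.phi = phi
        self.N, self.T = Y.shape
        self.sample_sigma = sample_sigma
        self.sample_gamma = sample_gamma
        self.positive = model.positive_params

        self.theta = np.array(theta0, dtype=float)
        self.z = _to_z(self.theta, self.positive)
        self.sigma2 = np.array(sigma2, dtype=float)
        self.u = np.array(u0, dtype=float)
        self.cache = [_SpeciesCache(eta0[s], t, gamma) for s in range(self.N)]
        self.accept = {"theta": [0, 0], "theta_ind": [0, 0], "eta": [0, 0],
                       "u": [0, 0], "sigma2": [0, 0], "gamma": [0, 0]}
        self.scales = {"theta": 0.1, "eta": 0.3, "u": 0.2, "sigma2": 0.3,
                       "gamma": 0.5}
        self._refresh_all()

    # -- state-derived quantities ------------------------------------------

    def set_gamma(self, gamma: float) -> None:
        """Switch the mismatch variance (burn-in annealing / INF updates)."""
        self.gamma = gamma
        for s, c in enumerate(self.cache):
            c.set_gamma(gamma)
        self.q = np.array([self._quad(s, self.F[s]) for s in range(self.N)])

    def _refresh_all(self) -> None:
        self.X = np.array([self.phi[s] + self.cache[s].L @ self.u[s]
                           for s in range(self.N)])
        self.F = np.asarray(self.model.rhs(self.X, self.theta, None))
        self.mu = np.array([self.cache[s].M @ self.u[s] for s in range(self.N)])
        self.q = np.array([self._quad(s, self.F[s]) for s in range(self.N)])
        self.data_terms = self._data_terms(self.X)
        self.lp_theta = self.priors.log_theta(self.theta)

    def _quad(self, s: int, f_s: np.ndarray) -> float:
        r = f_s - self.mu[s]
        return float(r @ self.cache[s].Binv @ r)

    def _data_terms(self, X: np.ndarray) -> np.ndarray:
        sq = ((self.Y - X) ** 2).sum(axis=1)
        return (-0.5 * sq / self.sigma2
                - 0.5 * self.T * (np.log(self.sigma2) + LOG2PI))

    # -- log-density pieces -------------------------------------------------

    def log_data(self) -> float:
        return float(self.data_terms.sum())

    def log_mismatch(self) -> float:
        logdets = sum(c.logdetB for c in self.cache)
        return -0.5 * (self.q.sum() + logdets + self.N * self.T * LOG2PI)

    def log_gp(self) -> float:
        # density of the whitened latents: the chain's state is u with
        # N(u|0,I) prior (the x-space GP normaliser cancels the |L_eta|
        # change-of-variables Jacobian)
        usq = float((self.u ** 2).sum())
        return -0.5 * (usq + self.N * self.T * LOG2PI)

    def log_priors_all(self) -> float:
        lp = self.lp_theta
        for c in self.cache:
            for h in c.spec.hyperparams:
                lp += self.priors.eta.logpdf(h)
        if self.sample_gamma:
            lp += self.priors.gamma.logpdf(self.gamma)
        if self.sample_sigma:
            lp += float(sum(self.priors.sigma2.logpdf(v) for v in self.sigma2))
        return lp

    def log_target(self) -> float:
        """Tempered log density of this chain's state at its own rung."""
        return (self.alpha * (self.log_data() + self.log_mismatch())
                + self.log_gp() + self.log_priors_all())


# ---------------------------------------------------------------------------
# Moves (module-level so they can be exercised directly)

def mh_update_theta(chain: Chain, rng: np.random.Generator,
                    scale: float | None = None,
                    component: int | None = None) -> bool:
    """Gaussian random-walk update of theta on the transformed scale.

    ``component`` restricts the move to a single parameter (componentwise
    updates mix better when the posterior is strongly correlated).
    """
    scale = chain.scales["theta"] if scale is None else scale
    if component is None:
        step = scale * rng.standard_normal(len(chain.z))
    else:
        step = np.zeros(len(chain.z))
        step[component] = scale * rng.standard_normal()
    z_new = chain.z + step
    theta_new = _to_theta(z_new, chain.positive)
    lp_new = chain.priors.log_theta(theta_new)
    chain.accept["theta"][1] += 1
    if not np.isfinite(lp_new):
        return False
    F_new = np.asarray(chain.model.rhs(chain.X, theta_new, None))
    q_new = np.array([chain._quad(s, F_new[s]) for s in range(chain.N)])
    delta = (chain.alpha * (-0.5) * (q_new.sum() - chain.q.sum())
             + (lp_new - chain.lp_theta)
             + (_log_jac(z_new, chain.positive) - _log_jac(chain.z, chain.positive)))
    if math.log(rng.random()) < delta:
        chain.z, chain.theta, chain.lp_theta = z_new, theta_new, lp_new
        chain.F, chain.q = F_new, q_new
        chain.accept["theta"][0] += 1
        return True
    return False


def mh_update_theta_prior_ind(chain: Chain, rng: np.random.Generator) -> bool:
    """Independence proposal from the prior; acceptance = tempered-lik ratio."""
    theta_new = chain.priors.sample_theta(rng)
    lp_new = chain.priors.log_theta(theta_new)
    chain.accept["theta_ind"][1] += 1
    if not np.isfinite(lp_new):
        return False
    F_new = np.asarray(chain.model.rhs(chain.X, theta_new, None))
    q_new = np.array([chain._quad(s, F_new[s]) for s in range(chain.N)])
    delta = chain.alpha * (-0.5) * (q_new.sum() - chain.q.sum())
    if math.log(rng.random()) < delta:
        chain.theta = theta_new
        chain.z = _to_z(theta_new, chain.positive)
        chain.lp_theta = lp_new
        chain.F, chain.q = F_new, q_new
        chain.accept["theta_ind"][0] += 1
        return True
    return False


def whitened_state_update(chain: Chain, rng: np.random.Generator,
                          n_latent_passes: int = 3,
                          sample_eta: bool = True) -> None:
    """Joint (eta_s, X) update keeping u fixed, then pCN updates of u_s."""
    if sample_eta:
        for s in range(chain.N):
            _eta_move(chain, s, rng)
    for _ in range(n_latent_passes):
        for s in range(chain.N):
            _u_move(chain, s, rng)


def _eta_move(chain: Chain, s: int, rng: np.random.Generator) -> bool:
    c = chain.cache[s]
    log_hp = np.log(c.spec.hyperparams)
    log_hp_new = log_hp + chain.scales["eta"] * rng.standard_normal(len(log_hp))
    chain.accept["eta"][1] += 1
    if np.any(np.abs(log_hp_new) > 25):
        return False
    spec_new = KernelSpec(c.spec.family, tuple(np.exp(log_hp_new)))
    try:
        cache_new = _SpeciesCache(spec_new, chain.t, chain.gamma)
    except Exception:
        return False
    x_s_new = chain.phi[s] + cache_new.L @ chain.u[s]
    X_new = chain.X.copy()
    X_new[s] = x_s_new
    F_new = np.asarray(chain.model.rhs(X_new, chain.theta, None))
    mu_new = chain.mu.copy()
    mu_new[s] = cache_new.M @ chain.u[s]
    caches = list(chain.cache)
    caches[s] = cache_new
    q_new = np.empty(chain.N)
    for k in range(chain.N):
        r = F_new[k] - mu_new[k]
        q_new[k] = float(r @ caches[k].Binv @ r)
    data_new = chain._data_terms(X_new)

    d_mis = (-0.5 * (q_new.sum() - chain.q.sum())
             - 0.5 * (cache_new.logdetB - c.logdetB))
    d_data = float(data_new.sum() - chain.data_terms.sum())
    # whitened move: u is the state, so the GP-prior factor N(u|0,I) is
    # untouched by changing eta (the |L_eta| Jacobian cancels the GP
    # normaliser); only likelihood, eta prior and proposal Jacobian enter
    d_prior = (sum(chain.priors.eta.logpdf(h) for h in spec_new.hyperparams)
               - sum(chain.priors.eta.logpdf(h) for h in c.spec.hyperparams))
    d_jac = float(log_hp_new.sum() - log_hp.sum())
    delta = chain.alpha * (d_data + d_mis) + d_prior + d_jac
    if math.log(rng.random()) < delta:
        chain.cache[s] = cache_new
        chain.X, chain.F, chain.mu, chain.q = X_new, F_new, mu_new, q_new
        chain.data_terms = data_new
        chain.accept["eta"][0] += 1
        return True
    return False


def _u_move(chain: Chain, s: int, rng: np.random.Generator) -> bool:
    """Preconditioned Crank-Nicolson proposal: preserves the whitened GP prior."""
    eps = min(chain.scales["u"], 0.999)
    u_s_new = (math.sqrt(1.0 - eps**2) * chain.u[s]
               + eps * rng.standard_normal(chain.T))
    chain.accept["u"][1] += 1
    x_s_new = chain.phi[s] + chain.cache[s].L @ u_s_new
    X_new = chain.X.copy()
    X_new[s] = x_s_new
    F_new = np.asarray(chain.model.rhs(X_new, chain.theta, None))
    mu_new = chain.mu.copy()
    mu_new[s] = chain.cache[s].M @ u_s_new
    q_new = np.empty(chain.N)
    for k in range(chain.N):
        r = F_new[k] - mu_new[k]
        q_new[k] = float(r @ chain.cache[k].Binv @ r)
    data_new = chain._data_terms(X_new)
    delta = chain.alpha * (float(data_new.sum() - chain.data_terms.sum())
                           - 0.5 * (q_new.sum() - chain.q.sum()))
    if math.log(rng.random()) < delta:
        chain.u[s] = u_s_new
        chain.X, chain.F, chain.mu, chain.q = X_new, F_new, mu_new, q_new
        chain.data_terms = data_new
        chain.accept["u"][0] += 1
        return True
    return False


def _sigma_move(chain: Chain, rng: np.random.Generator) -> bool:
    log_s2 = np.log(chain.sigma2)
    log_s2_new = log_s2 + chain.scales["sigma2"] * rng.standard_normal(chain.N)
    chain.accept["sigma2"][1] += 1
    s2_new = np.exp(log_s2_new)
    sq = ((chain.Y - chain.X) ** 2).sum(axis=1)
    data_new = -0.5 * sq / s2_new - 0.5 * chain.T * (np.log(s2_new) + LOG2PI)
    d_prior = float(sum(chain.priors.sigma2.logpdf(v) for v in s2_new)
                    - sum(chain.priors.sigma2.logpdf(v) for v in chain.sigma2))
    d_jac = float(log_s2_new.sum() - log_s2.sum())
    delta = (chain.alpha * float(data_new.sum() - chain.data_terms.sum())
             + d_prior + d_jac)
    if math.log(rng.random()) < delta:
        chain.sigma2 = s2_new
        chain.data_terms = data_new
        chain.accept["sigma2"][0] += 1
        return True
    return False


def _gamma_move(chain: Chain, rng: np.random.Generator) -> bool:
    g = chain.gamma
    g_new = math.exp(math.log(g) + chain.scales["gamma"] * rng.standard_normal())
    chain.accept["gamma"][1] += 1
    parts = [c.mismatch_quad_parts(g_new) for c in chain.cache]
    q_new = np.array([float((chain.F[s] - chain.mu[s]) @ parts[s][0]
                            @ (chain.F[s] - chain.mu[s]))
                      for s in range(chain.N)])
    logdetB_new = sum(p[1] for p in parts)
    logdetB_old = sum(c.logdetB for c in chain.cache)
    d_mis = -0.5 * ((q_new.sum() - chain.q.sum()) + (logdetB_new - logdetB_old))
    d_prior = chain.priors.gamma.logpdf(g_new) - chain.priors.gamma.logpdf(g)
    d_jac = math.log(g_new) - math.log(g)
    delta = chain.alpha * d_mis + d_prior + d_jac
    if math.log(rng.random()) < delta:
        chain.gamma = g_new
        for s, c in enumerate(chain.cache):
            c.Binv, _ldb = parts[s][0], parts[s][1]
            c.logdetB = parts[s][1]
        chain.q = q_new
        chain.accept["gamma"][0] += 1
        return True
    return False


def refine_latents(chain: Chain, weights: Sequence[float] = (1.0, 0.3, 0.1),
                   max_nfev: int = 4000) -> None:
    """Gradient-consistent initialisation of the whitened latents.

    Damped least squares drives the states toward the manifold where the
    interpolant's conditional derivatives match the ODE gradients at the
    chain's current theta, while a data term (annealed through ``weights``)
    keeps them faithful to the observations.  Purely an initialisation
    device: the subsequent MCMC targets the unmodified tempered density.
    """
    from scipy.optimize import least_squares

    N, T = chain.N, chain.T
    phi, Y, sig2 = chain.phi, chain.Y, chain.sigma2
    Ls = [c.L for c in chain.cache]
    Ms = [c.M for c in chain.cache]
    theta = chain.theta

    def resid(uflat: np.ndarray, w: float) -> np.ndarray:
        u = uflat.reshape(N, T)
        X = np.array([phi[s] + Ls[s] @ u[s] for s in range(N)])
        F = np.asarray(chain.model.rhs(X, theta, None))
        parts = []
        for s in range(N):
            parts.append(F[s] - Ms[s] @ u[s])
            parts.append(w * (Y[s] - X[s]) / np.sqrt(sig2[s]))
            parts.append(0.2 * u[s])
        return np.concatenate(parts)

    u = chain.u.ravel().copy()
    try:
        for w in weights:
            u = least_squares(resid, u, args=(w,), method="lm",
                              max_nfev=max_nfev).x
    except Exception:
        return  # keep the GP-regression initialisation
    if np.all(np.isfinite(u)):
        chain.u = u.reshape(N, T)
        chain._refresh_all()


_SWAP_FIELDS = ("theta", "z", "lp_theta", "u", "cache", "X", "F", "mu", "q",
                "data_terms", "sigma2")


def propose_swap(chains: Sequence[Chain], i: int, j: int,
                 rng: np.random.Generator, sample_gamma: bool = False) -> bool:
    """Propose exchanging the full states of rungs i and j."""
    ci, cj = chains[i], chains[j]
    if sample_gamma:
        # gamma travels with the state; only alpha differs between rungs
        di = ci.log_data() + ci.log_mismatch()
        dj = cj.log_data() + cj.log_mismatch()
        delta = (ci.alpha - cj.alpha) * (dj - di)
        cross = None
    else:
        # each rung keeps its own gamma: re-evaluate each state's mismatch
        # under the other rung's gamma
        def mis_under(chain: Chain, gamma: float):
            parts = [c.mismatch_quad_parts(gamma) for c in chain.cache]
            q = np.array([float((chain.F[s] - chain.mu[s]) @ parts[s][0]
                                @ (chain.F[s] - chain.mu[s]))
                          for s in range(chain.N)])
            logdet = sum(p[1] for p in parts)
            val = -0.5 * (q.sum() + logdet + chain.N * chain.T * LOG2PI)
            return val, parts, q
        mis_j_under_i, parts_j, q_j = mis_under(cj, ci.gamma)
        mis_i_under_j, parts_i, q_i = mis_under(ci, cj.gamma)
        delta = (ci.alpha * (cj.log_data() + mis_j_under_i)
                 + cj.alpha * (ci.log_data() + mis_i_under_j)
                 - ci.alpha * (ci.log_data() + ci.log_mismatch())
                 - cj.alpha * (cj.log_data() + cj.log_mismatch()))
        cross = (parts_i, q_i, parts_j, q_j)
    if math.log(rng.random()) < delta:
        for name in _SWAP_FIELDS:
            tmp = getattr(ci, name)
            setattr(ci, name, getattr(cj, name))
            setattr(cj, name, tmp)
        if sample_gamma:
            ci.gamma, cj.gamma = cj.gamma, ci.gamma
        else:
            # states moved to new rungs: install the mismatch geometry that
            # was evaluated under each rung's own gamma
            parts_i, q_i, parts_j, q_j = cross
            for s, c in enumerate(ci.cache):   # ci now holds old state j
                c.Binv, c.logdetB = parts_j[s]
            ci.q = q_j
            for s, c in enumerate(cj.cache):   # cj now holds old state i
                c.Binv, c.logdetB = parts_i[s]
            cj.q = q_i
        return True
    return False


# ---------------------------------------------------------------------------

@dataclass
class SamplerOutput:
    theta_target: np.ndarray          # (n_kept, P) samples at alpha = 1
    theta_prior_chain: np.ndarray     # (n_kept, P) samples at alpha = 0
    accept_rates: dict
    swap_accept_rate: float
    log_joint_trace: np.ndarray
    seed: int
    config: dict
    initial_theta: np.ndarray
    param_names: tuple[str, ...] = ()
    final_states: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.theta_target.shape[0]

    def posterior_median(self) -> np.ndarray:
        if self.n_samples == 0:
            raise ValueError("no retained samples")
        return np.median(self.theta_target, axis=0)


def _adapt(chain: Chain, window: dict) -> None:
    for move, scale_key in (("theta", "theta"), ("eta", "eta"), ("u", "u"),
                            ("sigma2", "sigma2"), ("gamma", "gamma")):
        acc, tot = window[move]
        if tot == 0:
            continue
        rate = acc / tot
        factor = math.exp(0.5 * (rate - 0.30))
        chain.scales[scale_key] = float(np.clip(chain.scales[scale_key] * factor,
                                                1e-4, 10.0))
        window[move] = [0, 0]


def run(dataset: Dataset, model: ODEModel, mode: str = "lb10", chains: int = 4,
        iterations: int = 20_000, burn_in: int | None = None, thin: int = 10,
        seed: int = 0, priors: PriorSet | None = None,
        kernel_family: str | None = None, fix_sigma: bool = True,
        sigma_true: np.ndarray | None = None, sample_eta: bool = True,
        gamma_start: float = 1.0) -> SamplerOutput:
    """Run the parallel-tempered gradient-matching sampler.

    ``mode`` selects the mismatch-variance handling: 'lb2'/'lb10' use fixed
    geometric ladders (base 2 / base 10, starting at 1); 'inf' samples gamma.
    ``fix_sigma`` holds the observation sd at the generating value (the
    known-noise regime); otherwise sigma^2 is sampled under a vague
    inverse-Gamma prior.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    burn_in = iterations // 2 if burn_in is None else burn_in
    priors = default_priors(model.name) if priors is None else priors
    kernel_family = kernel_family or ("rbf" if model.name == "fhn"
                                     else "sigmoid_variance")
    rng = np.random.default_rng(seed)
    t, Y = dataset.t, dataset.Y
    N, T = Y.shape
    phi = np.repeat(Y.mean(axis=1)[:, None], T, axis=1)

    alphas = make_alpha_ladder(chains)
    if mode == "inf":
        gammas = np.full(chains, gamma_start)
        sample_gamma = True
    else:
        gammas = make_gamma_ladder(chains, 2 if mode == "lb2" else 10, gamma_start)
        sample_gamma = False

    # eta initialisation by ML GP regression per species
    fits: list[GPFitResult] = []
    for s in range(N):
        fixed = float(dataset.realized_sd[s]) if fix_sigma else None
        fits.append(gp_fit_ml(t, Y[s], family=kernel_family, noise_sd=fixed,
                              seed=int(rng.integers(2**31 - 1))))
    if fix_sigma:
        if sigma_true is None:
            sigma_true = np.asarray(dataset.realized_sd, float)
        sigma2 = np.asarray(sigma_true, float) ** 2
    else:
        sigma2 = np.array([max(f.noise_sd, 1e-3) ** 2 for f in fits])

    # initial latents: whitened GP-regression posterior mean,
    # u0 = L' (K + sigma^2 I)^{-1} (y - phi), which is data-consistent and
    # has moderate norm under the whitened N(0, I) prior by construction
    u0 = np.empty((N, T))
    for s in range(N):
        Kmat = kernel_eval(fits[s].spec, t[:, None], t[None, :])
        L = chol_with_jitter(Kmat)
        u0[s] = L.T @ linalg.solve(Kmat + sigma2[s] * np.eye(T),
                                   Y[s] - phi[s], assume_a="pos")

    # theta initialised from the prior
    theta0 = priors.sample_theta(rng)

    chain_list = [
        Chain(alpha=float(alphas[i]), gamma=float(gammas[i]), model=model,
              priors=priors, t=t, Y=Y, phi=phi, theta0=theta0,
              eta0=[f.spec for f in fits], sigma2=sigma2, u0=u0,
              sample_sigma=not fix_sigma, sample_gamma=sample_gamma)
        for i in range(chains)
    ]

    kept_target: list[np.ndarray] = []
    kept_prior: list[np.ndarray] = []
    trace: list[float] = []
    swap_acc = swap_tot = 0
    windows = [{m: [0, 0] for m in ("theta", "eta", "u", "sigma2", "gamma")}
               for _ in range(chains)]

    # theta-only warm-up: let each chain's parameters adapt to the initial
    # interpolant before the latent states are allowed to move (otherwise
    # an arbitrary prior draw of theta can flatten the states irreversibly)
    warmup = min(500, burn_in // 4) if iterations > 0 else 0
    for sweep in range(warmup):
        for chain in chain_list:
            mh_update_theta(chain, rng)
            mh_update_theta(chain, rng,
                            component=int(rng.integers(model.n_params)))
            if sweep % 10 == 0:
                mh_update_theta_prior_ind(chain, rng)
        if sweep % 50 == 49:
            for ci, chain in enumerate(chain_list):
                acc, tot = chain.accept["theta"]
                rate = acc / max(tot, 1)
                chain.scales["theta"] = float(np.clip(
                    chain.scales["theta"] * math.exp(0.5 * (rate - 0.30)),
                    1e-4, 10.0))

    # gradient-consistent latent initialisation at each chain's warmed-up
    # theta (hot chains barely feel it; for cold chains it prevents a slow
    # drift into the flattening attractor the likelihood cannot escape)
    if iterations > 0:
        for chain in chain_list:
            refine_latents(chain)

    for sweep in range(iterations):
        for ci, chain in enumerate(chain_list):
            before = {m: tuple(chain.accept[m]) for m in windows[ci]}
            mh_update_theta(chain, rng)
            mh_update_theta(chain, rng,
                            component=int(rng.integers(model.n_params)))
            if sweep % 10 == 0:
                mh_update_theta_prior_ind(chain, rng)
            whitened_state_update(chain, rng, sample_eta=sample_eta)
            if chain.sample_sigma:
                _sigma_move(chain, rng)
            if chain.sample_gamma:
                _gamma_move(chain, rng)
            for m in windows[ci]:
                a0, t0 = before[m]
                windows[ci][m][0] += chain.accept[m][0] - a0
                windows[ci][m][1] += chain.accept[m][1] - t0
        if chains >= 2:
            i, j = rng.choice(chains, size=2, replace=False)
            swap_tot += 1
            swap_acc += propose_swap(chain_list, int(i), int(j), rng,
                                     sample_gamma=sample_gamma)
        if sweep < burn_in and sweep % 50 == 49:
            for ci, chain in enumerate(chain_list):
                _adapt(chain, windows[ci])
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            kept_target.append(chain_list[-1].theta.copy())
            kept_prior.append(chain_list[0].theta.copy())
            trace.append(chain_list[-1].log_target())

    def rates(chain: Chain) -> dict:
        return {m: (a / tot if tot else float("nan"))
                for m, (a, tot) in chain.accept.items()}

    return SamplerOutput(
        theta_target=np.array(kept_target).reshape(len(kept_target), -1)
        if kept_target else np.empty((0, model.n_params)),
        theta_prior_chain=np.array(kept_prior).reshape(len(kept_prior), -1)
        if kept_prior else np.empty((0, model.n_params)),
        accept_rates={f"chain{idx}": rates(c) for idx, c in enumerate(chain_list)},
        swap_accept_rate=(swap_acc / swap_tot) if swap_tot else float("nan"),
        log_joint_trace=np.array(trace),
        seed=seed,
        config={"mode": mode, "chains": chains, "iterations": iterations,
                "burn_in": burn_in, "thin": thin, "fix_sigma": fix_sigma,
                "kernel_family": kernel_family,
                "alphas": alphas.tolist(), "gammas": gammas.tolist()},
        initial_theta=theta0,
        param_names=model.params,
        final_states=[{
            "alpha": c.alpha, "gamma": c.gamma, "theta": c.theta.copy(),
            "X": c.X.copy(), "sigma2": c.sigma2.copy(),
            "eta": [tuple(cc.spec.hyperparams) for cc in c.cache],
            "scales": dict(c.scales), "q": c.q.copy(),
            "log_data": c.log_data(), "log_mismatch": c.log_mismatch(),
        } for c in chain_list],
    )
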