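"""Adaptive gradient-matching joint density.

The model links a GP interpolant with the ODE through a product of experts
on the state derivatives.  Marginalising the derivatives in closed form
(a Gaussian convolution) gives, per species,

    p(x_s | theta, phi, eta, gamma)
        = N(x_s | phi_s, K_eta)  *  N(f_s | mu_s, A_s + gamma I) ,

where f_s is the ODE-predicted gradient at the latent states, (mu_s, A_s)
the GP conditional of derivatives given states, and gamma the gradient
mismatch variance: gamma = 0 forces the interpolant slopes to agree exactly
with the ODE, large gamma decouples them.  The data enter through an iid
Gaussian observation model y = x + eps.

Both Gaussian factors keep their full normalising constants so that the
density is comparable across GP hyperparameters eta, which are sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, special

from .gp_interpolation import DerivConditional, GPBlocks, chol_with_jitter
from .ode_models import ODEModel

LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Lightweight priors (numpy logpdf + rvs; cheap enough for inner MCMC loops)

class Prior:
    support_positive = False

    def logpdf(self, x: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def rvs(self, rng: np.random.Generator) -> float:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class NormalPrior(Prior):
    mean: float
    sd: float
    support_positive = False

    def logpdf(self, x):
        z = (x - self.mean) / self.sd
        return -0.5 * z * z - math.log(self.sd) - 0.5 * LOG2PI

    def rvs(self, rng):
        return self.mean + self.sd * rng.standard_normal()


@dataclass(frozen=True)
class GammaPrior(Prior):
    """Gamma with shape/scale parameterisation (mean = shape * scale)."""
    shape: float
    scale: float
    support_positive = True

    def logpdf(self, x):
        if x <= 0:
            return -np.inf
        return ((self.shape - 1.0) * math.log(x) - x / self.scale
                - special.gammaln(self.shape) - self.shape * math.log(self.scale))

    def rvs(self, rng):
        return rng.gamma(self.shape, self.scale)


@dataclass(frozen=True)
class ChiSquarePrior(Prior):
    df: float
    support_positive = True

    def logpdf(self, x):
        if x <= 0:
            return -np.inf
        k = self.df / 2.0
        return (k - 1.0) * math.log(x) - x / 2.0 - special.gammaln(k) - k * math.log(2.0)

    def rvs(self, rng):
        return rng.chisquare(self.df)


@dataclass(frozen=True)
class InverseGammaPrior(Prior):
    """Vague prior for observation variances (shape 2, scale 1 by default)."""
    shape: float = 2.0
    scale: float = 1.0
    support_positive = True

    def logpdf(self, x):
        if x <= 0:
            return -np.inf
        return (self.shape * math.log(self.scale) - special.gammaln(self.shape)
                - (self.shape + 1.0) * math.log(x) - self.scale / x)

    def rvs(self, rng):
        return self.scale / rng.gamma(self.shape, 1.0)


@dataclass(frozen=True)
class LogNormalPrior(Prior):
    """Weak prior for GP hyperparameters (on their natural positive scale)."""
    mu: float = 0.0
    sigma: float = 2.0
    support_positive = True

    def logpdf(self, x):
        if x <= 0:
            return -np.inf
        z = (math.log(x) - self.mu) / self.sigma
        return -0.5 * z * z - math.log(x * self.sigma) - 0.5 * LOG2PI

    def rvs(self, rng):
        return math.exp(self.mu + self.sigma * rng.standard_normal())


@dataclass(frozen=True)
class PriorSet:
    """Priors for theta (per parameter), eta, gamma and sigma^2."""

    theta: tuple[Prior, ...]
    eta: Prior = field(default_factory=LogNormalPrior)
    gamma: Prior = field(default_factory=lambda: GammaPrior(1.0, 1.0))
    sigma2: Prior = field(default_factory=InverseGammaPrior)

    def log_theta(self, theta: np.ndarray) -> float:
        return float(sum(p.logpdf(v) for p, v in zip(self.theta, theta)))

    def sample_theta(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([p.rvs(rng) for p in self.theta])


def default_priors(model_name: str) -> PriorSet:
    """Benchmark priors: FitzHugh-Nagumo alpha, beta ~ N(0, 0.4^2), psi ~
    chi^2_2; pathway rate constants ~ Gamma(4, scale 0.5)."""
    if model_name == "fhn":
        return PriorSet(theta=(NormalPrior(0.0, 0.4), NormalPrior(0.0, 0.4),
                               ChiSquarePrior(2.0)))
    if model_name == "ptp":
        return PriorSet(theta=tuple(GammaPrior(4.0, 0.5) for _ in range(6)))
    raise KeyError(f"no default priors for model {model_name!r}")


# ---------------------------------------------------------------------------
# Density components

def log_data_likelihood(Y: np.ndarray, X: np.ndarray, sigma2: np.ndarray) -> float:
    """Sum of iid Gaussian log densities, per species and timepoint."""
    Y = np.asarray(Y, float)
    X = np.asarray(X, float)
    sigma2 = np.atleast_1d(np.asarray(sigma2, float))
    if Y.shape != X.shape:
        raise ValueError("Y and X shapes disagree")
    if np.any(sigma2 <= 0):
        raise ValueError("observation variances must be positive")
    T = Y.shape[1]
    sq = ((Y - X) ** 2).sum(axis=1)
    return float((-0.5 * sq / sigma2 - 0.5 * T * (np.log(sigma2) + LOG2PI)).sum())


def _logdet_from_chol(L: np.ndarray) -> float:
    return 2.0 * float(np.log(np.diag(L)).sum())


def log_gp_prior_term(X: np.ndarray, blocks: Sequence[GPBlocks]) -> float:
    """sum_s log N(x_s | phi_s, K_{eta_s})."""
    total = 0.0
    for s, b in enumerate(blocks):
        L = chol_with_jitter(b.K)
        resid = X[s] - b.phi
        alpha = linalg.cho_solve((L, True), resid)
        T = len(resid)
        total += -0.5 * float(resid @ alpha) - 0.5 * _logdet_from_chol(L) - 0.5 * T * LOG2PI
    return total


def log_mismatch_term(X: np.ndarray, theta: np.ndarray, model: ODEModel,
                      conds: Sequence[DerivConditional], gamma: float,
                      F: np.ndarray | None = None) -> float:
    """sum_s log N(f_s | mu_s, A_s + gamma I): the gradient-match factor."""
    if F is None:
        F = model.rhs(X, theta, None)
    total = 0.0
    for s, cond in enumerate(conds):
        B = cond.A + gamma * np.eye(cond.A.shape[0])
        try:
            L = linalg.cholesky(B, lower=True)
        except linalg.LinAlgError:
            L = chol_with_jitter(B, what="A + gamma*I")
        r = F[s] - cond.mu
        alpha = linalg.cho_solve((L, True), r)
        T = len(r)
        total += -0.5 * float(r @ alpha) - 0.5 * _logdet_from_chol(L) - 0.5 * T * LOG2PI
    return total


def log_px_marginal(X: np.ndarray, theta: np.ndarray, model: ODEModel,
                    blocks: Sequence[GPBlocks], conds: Sequence[DerivConditional],
                    gamma: float) -> float:
    """Closed-form log p(X | theta, phi, eta, gamma): GP prior x gradient match."""
    return (log_gp_prior_term(X, blocks)
            + log_mismatch_term(X, theta, model, conds, gamma))


def log_joint(Y: np.ndarray, X: np.ndarray, theta: np.ndarray, model: ODEModel,
              blocks: Sequence[GPBlocks], conds: Sequence[DerivConditional],
              gamma: float, sigma2: np.ndarray, priors: PriorSet,
              eta_values: Sequence[float] = (), sample_sigma: bool = False,
              sample_gamma: bool = False) -> float:
    """Full joint log density of (Y, X, theta, eta, [gamma, sigma^2])."""
    lp = priors.log_theta(theta)
    if not np.isfinite(lp):
        return -np.inf
    for h in eta_values:
        lp += priors.eta.logpdf(h)
    if sample_gamma:
        lp += priors.gamma.logpdf(gamma)
    if sample_sigma:
        lp += float(sum(priors.sigma2.logpdf(v) for v in np.atleast_1d(sigma2)))
    if not np.isfinite(lp):
        return -np.inf
    return (lp + log_data_likelihood(Y, X, sigma2)
            + log_px_marginal(X, theta, model, blocks, conds, gamma))
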