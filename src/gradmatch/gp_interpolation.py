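"""Gaussian-process interpolation with analytic derivative covariances.

A GP prior is placed on each species' concentration profile.  Because
differentiation is linear, the GP is closed under it: the joint law of
states x and their time derivatives xdot is Gaussian with blocks

    K   = cov[x, x]        K'  = cov[xdot, x]  (partial wrt t_i)
    'K  = cov[x, xdot]     K'' = cov[xdot, xdot]

and the conditional xdot | x is N(mu, A) with

    mu = 'K K^{-1} (x - phi),     A = K'' - 'K K^{-1} K'.

Two kernel families are implemented with hand-derived partials:

* RBF          k = s2 * exp(-(ti-tj)^2 / (2 l2)) -- stationary; a good fit
  for the periodic FitzHugh--Nagumo signals.
* sigmoid variance ("neural network") kernel
  k = s2 * arcsin( (a + b ti tj) / sqrt((a + b ti^2 + 1)(a + b tj^2 + 1)) )
  -- non-stationary; suits the transduction pathway's transition to a
  stationary phase, which the RBF kernel cannot represent properly.

For the sigmoid kernel, writing num = a + b ti tj, d_i = a + b ti^2 + 1 and
P = d_i d_j - num^2, the partials collapse to

    dk/dti      = s2 * b * (tj d_i - ti num) / (d_i sqrt(P))
    d2k/dtidtj  = s2 * b * (2a + 1) / P^(3/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

KERNEL_FAMILIES = ("rbf", "sigmoid_variance")

#: jitter added to K as a fraction of mean(diag), escalated x10 until PD
JITTER_START = 1e-8
JITTER_MAX = 1e-4


class KernelError(ValueError):
    pass


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus hyperparameters.

    rbf: ``(s2, l2)`` signal variance and squared length scale.
    sigmoid_variance: ``(s2, a, b)``.
    """

    family: str
    hyperparams: tuple[float, ...]

    def __post_init__(self):
        if self.family not in KERNEL_FAMILIES:
            raise KernelError(f"unknown kernel family {self.family!r}")
        n_expected = 2 if self.family == "rbf" else 3
        hp = tuple(float(h) for h in self.hyperparams)
        if len(hp) != n_expected:
            raise KernelError(f"{self.family} kernel takes {n_expected} hyperparameters")
        if any(h <= 0 for h in hp):
            raise KernelError("kernel hyperparameters must be positive")
        object.__setattr__(self, "hyperparams", hp)


@dataclass(frozen=True)
class GPBlocks:
    """The four T x T covariance blocks of (x, xdot) plus the mean phi."""

    K: np.ndarray
    Kp: np.ndarray    # cov[xdot(t_i), x(t_j)]
    pK: np.ndarray    # cov[x(t_i), xdot(t_j)] == Kp.T
    Kpp: np.ndarray   # cov[xdot, xdot]
    phi: float = 0.0


@dataclass(frozen=True)
class DerivConditional:
    mu: np.ndarray
    A: np.ndarray


def kernel_eval(spec: KernelSpec, t_i, t_j):
    """Covariance k(t_i, t_j); inputs broadcast."""
    t_i = np.asarray(t_i, dtype=float)
    t_j = np.asarray(t_j, dtype=float)
    if spec.family == "rbf":
        s2, l2 = spec.hyperparams
        return s2 * np.exp(-((t_i - t_j) ** 2) / (2.0 * l2))
    s2, a, b = spec.hyperparams
    num = a + b * t_i * t_j
    di = a + b * t_i**2 + 1.0
    dj = a + b * t_j**2 + 1.0
    arg = num / np.sqrt(di * dj)
    if np.any(np.abs(arg) > 1.0 + 1e-12):
        raise KernelError("arcsin argument outside [-1, 1] beyond tolerance")
    return s2 * np.arcsin(np.clip(arg, -1.0, 1.0))


def kernel_derivative_blocks(spec: KernelSpec, t: np.ndarray, phi: float = 0.0) -> GPBlocks:
    """Assemble K, K', 'K, K'' on the grid from analytic kernel partials."""
    t = np.asarray(t, dtype=float)
    ti = t[:, None]
    tj = t[None, :]
    if spec.family == "rbf":
        s2, l2 = spec.hyperparams
        d = ti - tj
        K = s2 * np.exp(-(d**2) / (2.0 * l2))
        Kp = -(d / l2) * K                 # d/dti
        pK = (d / l2) * K                  # d/dtj
        Kpp = (1.0 / l2 - d**2 / l2**2) * K
    else:
        s2, a, b = spec.hyperparams
        num = a + b * ti * tj
        di = a + b * ti**2 + 1.0
        dj = a + b * tj**2 + 1.0
        P = di * dj - num**2
        sqrtP = np.sqrt(P)
        K = s2 * np.arcsin(np.clip(num / np.sqrt(di * dj), -1.0, 1.0))
        Kp = s2 * b * (tj * di - ti * num) / (di * sqrtP)   # d/dti
        pK = s2 * b * (ti * dj - tj * num) / (dj * sqrtP)   # d/dtj
        Kpp = s2 * b * (2.0 * a + 1.0) / P**1.5
    return GPBlocks(K=K, Kp=Kp, pK=pK, Kpp=Kpp, phi=phi)


def chol_with_jitter(K: np.ndarray, what: str = "K"):
    """Cholesky factor of K + jitter*I, escalating jitter until PD."""
    scale = float(np.mean(np.diag(K)))
    jitter = JITTER_START
    while jitter <= JITTER_MAX:
        try:
            return linalg.cholesky(K + jitter * scale * np.eye(K.shape[0]), lower=True)
        except linalg.LinAlgError:
            jitter *= 10.0
    raise KernelError(f"{what} not positive definite even at jitter {JITTER_MAX}")


def deriv_conditional(blocks: GPBlocks, x: np.ndarray) -> DerivConditional:
    """Conditional N(mu, A) of derivatives given states, via Cholesky solves.

    Standard Gaussian conditioning on the joint (xdot, x) law:
    mu = cov(xdot, x) K^{-1} (x - phi) and
    A = K'' - cov(xdot, x) K^{-1} cov(x, xdot),
    where cov(xdot, x) is the d/dt_i block (``Kp``).
    """
    L = chol_with_jitter(blocks.K)
    resid = np.asarray(x, dtype=float) - blocks.phi
    Kinv_resid = linalg.cho_solve((L, True), resid)
    mu = blocks.Kp @ Kinv_resid
    Kinv_pK = linalg.cho_solve((L, True), blocks.pK)
    A = blocks.Kpp - blocks.Kp @ Kinv_pK
    A = 0.5 * (A + A.T)
    return DerivConditional(mu=mu, A=A)


# ---------------------------------------------------------------------------
# Maximum-likelihood GP regression fit (hyperparameter initialisation)

def gp_log_marginal(spec: KernelSpec, t: np.ndarray, y: np.ndarray,
                    noise_sd: float) -> float:
    """Standard GP regression marginal log-likelihood with mean = sample mean."""
    y = np.asarray(y, dtype=float)
    K = kernel_eval(spec, t[:, None], t[None, :]) + noise_sd**2 * np.eye(len(t))
    try:
        L = linalg.cholesky(K + JITTER_START * np.eye(len(t)), lower=True)
    except linalg.LinAlgError:
        return -np.inf
    resid = y - y.mean()
    alpha = linalg.cho_solve((L, True), resid)
    return float(-0.5 * resid @ alpha - np.log(np.diag(L)).sum()
                 - 0.5 * len(t) * np.log(2.0 * np.pi))


@dataclass(frozen=True)
class GPFitResult:
    spec: KernelSpec
    noise_sd: float
    log_marginal: float
    converged: bool


def gp_fit_ml(t: np.ndarray, y: np.ndarray, family: str = "rbf",
              noise_sd: float | None = None, n_starts: int = 8,
              seed: int = 0) -> GPFitResult:
    """Fit kernel hyperparameters (and optionally the noise sd) by maximum
    likelihood with multi-start L-BFGS on the log-hyperparameter scale.

    ``noise_sd=None`` estimates the observation noise jointly; passing a
    value holds it fixed (the regime where the noise level is known).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 observations for a GP fit")
    rng = np.random.default_rng(seed)
    span = t.max() - t.min()
    var = max(y.var(ddof=1), 1e-12)
    fit_noise = noise_sd is None

    n_kernel = 2 if family == "rbf" else 3

    def unpack(z):
        hp = tuple(np.exp(z[:n_kernel]))
        sd = np.exp(z[n_kernel]) if fit_noise else noise_sd
        return KernelSpec(family, hp), sd

    def neg_loglik(z):
        if np.any(np.abs(z) > 25):
            return 1e10
        spec, sd = unpack(z)
        val = gp_log_marginal(spec, t, y, sd)
        return 1e10 if not np.isfinite(val) else -val

    # initial ranges centred on data scales
    if family == "rbf":
        centers = np.log([var, (0.1 * span) ** 2])
    else:
        centers = np.log([var, 1.0, 1.0 / max(span, 1.0) ** 2])
    if fit_noise:
        centers = np.append(centers, np.log(np.sqrt(var) * 0.2))

    best = None
    for k in range(n_starts):
        z0 = centers + (rng.standard_normal(len(centers)) if k else 0.0)
        res = optimize.minimize(neg_loglik, z0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success) and best.fun < 1e9
    if not converged:
        warnings.warn("GP hyperparameter optimisation did not converge; "
                      "returning best point found", RuntimeWarning)
    spec, sd = unpack(best.x)
    return GPFitResult(spec=spec, noise_sd=float(sd),
                       log_marginal=float(-best.fun), converged=converged)
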