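"""RKHS penalised-likelihood estimation for ODE parameters.

The ODE is written per species as xdot_s = g_s(X, rho_s, t) - delta_s x_s,
isolating a linear decay rate delta_s.  Time differentiation is
approximated by a first-order differencing operator D on the observation
grid, so R x_s ~ g_s with R = D + delta_s I.  Transforming the states and
data by subtracting R^{-1} g_s turns the gradient-match penalty into a
proper RKHS norm ||R xtilde||^2 = xtilde' R'R xtilde with reproducing
kernel K = (R'R)^{-1}, and the penalised maximum-likelihood states have
the closed ridge form

    xtilde_s = K (K + 2 lambda_s Sigma)^{-1} ytilde_s .

The non-linear part g_s is linearised by evaluating it on a smoothing-
spline surrogate of the data, so the objective is cheap to evaluate and
the ODE never has to be integrated.  The penalised log-likelihood is
maximised over the ODE parameters with multi-start quasi-Newton; the
penalty lambda is chosen per species either by AIC or by threefold
cross-validation with interleaved folds (the CV route skips any lambda for
which the ridge system is numerically singular, which is what rescues the
method on the transduction pathway).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, linalg, optimize

from .agm_posterior import PriorSet, default_priors
from .ode_models import ODEModel
from .synthetic_data import Dataset

LOG2PI = math.log(2.0 * math.pi)

#: default log-spaced penalty grid
DEFAULT_LAMBDA_GRID = np.logspace(-6, 3, 19)

#: condition-number ceiling above which a lambda is treated as singular
_COND_MAX = 1e12

#: candidate floors on the per-species decay rate used to build
#: R = D + delta*I.  The differencing matrix D annihilates constants (and,
#: on equispaced grids, nearly annihilates alternating vectors), so R is
#: singular or severely ill-conditioned for species with little or no
#: linear decay.  The decay split is not unique: for delta below the floor
#: the deficit (floor - delta)*xhat_s is moved into g_s, evaluated on the
#: spline surrogate like the rest of the non-linear part.  The smallest
#: floor keeping R'R comfortably invertible on the given grid is used.
_DELTA_FLOOR_GRID = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5)
_DELTA_COND_TARGET = 1e11


class RejectedLambda(RuntimeError):
    """The ridge system (K + 2*lambda*Sigma) is numerically singular."""


def delta_floor_for_grid(diff: "DiffOperator") -> float:
    """Smallest candidate decay floor keeping (D + delta I)'(D + delta I)
    well-conditioned on this grid."""
    T = len(diff.t)
    for floor in _DELTA_FLOOR_GRID:
        R = diff.D + floor * np.eye(T)
        if np.linalg.cond(R.T @ R) < _DELTA_COND_TARGET:
            return floor
    return _DELTA_FLOOR_GRID[-1]


@dataclass(frozen=True)
class DiffOperator:
    """First-order difference-quotient matrix on a (possibly irregular) grid.

    Row 1 is a forward difference over (t1, t2), rows 2..T-1 central
    differences over (t_{r-1}, t_{r+1}), and the last row a backward
    difference over (t_{T-1}, t_T).  Applied to the grid itself, each row
    yields exactly 1.
    """

    t: np.ndarray
    D: np.ndarray
    Delta: np.ndarray
    delta_floor: float = 0.0


def build_D(t: np.ndarray) -> DiffOperator:
    t = np.asarray(t, dtype=float)
    T = len(t)
    if T < 3:
        raise ValueError("need at least 3 timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    S = np.zeros((T, T))
    spans = np.empty(T)
    S[0, 0], S[0, 1] = -1.0, 1.0
    spans[0] = t[1] - t[0]
    for r in range(1, T - 1):
        S[r, r - 1], S[r, r + 1] = -1.0, 1.0
        spans[r] = t[r + 1] - t[r - 1]
    S[T - 1, T - 2], S[T - 1, T - 1] = -1.0, 1.0
    spans[T - 1] = t[T - 1] - t[T - 2]
    Delta = np.diag(1.0 / spans)
    diff = DiffOperator(t=t, D=Delta @ S, Delta=Delta)
    object.__setattr__(diff, "delta_floor", delta_floor_for_grid(diff))
    return diff


@dataclass
class RKHSProblem:
    """Per-species linear-algebra workspace at fixed (delta_s, lambda_s)."""

    t: np.ndarray
    R: np.ndarray
    K: np.ndarray
    Sigma: np.ndarray
    lambda_s: float

    @classmethod
    def build(cls, diff: DiffOperator, delta_s: float, sigma2_s: float,
              lambda_s: float) -> "RKHSProblem":
        T = len(diff.t)
        R = diff.D + delta_s * np.eye(T)
        RtR = R.T @ R
        # only an (almost) exactly singular R is fatal here; a merely
        # ill-conditioned K may still be usable once 2*lambda*Sigma
        # regularises the ridge system (checked where it is inverted)
        if np.linalg.cond(RtR) > 1e15:
            raise RejectedLambda(f"R'R singular at delta={delta_s}")
        K = np.linalg.inv(RtR)
        K = 0.5 * (K + K.T)
        return cls(t=diff.t, R=R, K=K, Sigma=sigma2_s * np.eye(T),
                   lambda_s=lambda_s)


def transform(problem: RKHSProblem, v: np.ndarray, g: np.ndarray) -> np.ndarray:
    """ytilde or xtilde: subtract R^{-1} g (solved, never inverted)."""
    try:
        shift = linalg.solve(problem.R, g)
    except linalg.LinAlgError as exc:
        raise RejectedLambda(f"R singular: {exc}") from exc
    return np.asarray(v, float) - shift


def untransform(problem: RKHSProblem, v_tilde: np.ndarray, g: np.ndarray) -> np.ndarray:
    return np.asarray(v_tilde, float) + linalg.solve(problem.R, g)


def penalty_omega(problem: RKHSProblem, x_tilde: np.ndarray) -> float:
    Rx = problem.R @ x_tilde
    return float(Rx @ Rx)


def solve_xtilde(problem: RKHSProblem, y_tilde: np.ndarray) -> np.ndarray:
    """Closed-form ridge solution K (K + 2 lambda Sigma)^{-1} ytilde.

    Evaluated in the equivalent primal form
    (Sigma^{-1} + 2 lambda R'R)^{-1} Sigma^{-1} ytilde (push-through
    identity), which avoids inverting R'R and stays accurate for small
    decay rates.  A system whose conditioning exceeds the ceiling raises
    :class:`RejectedLambda`.
    """
    Sinv = np.diag(1.0 / np.diag(problem.Sigma))
    Msys = Sinv + 2.0 * problem.lambda_s * (problem.R.T @ problem.R)
    if np.linalg.cond(Msys) > _COND_MAX:
        raise RejectedLambda(
            f"singular ridge system at lambda={problem.lambda_s}")
    return linalg.solve(Msys, Sinv @ y_tilde, assume_a="sym")


def fit_surrogate(t: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, list]:
    """Cubic smoothing-spline surrogate per species (GCV smoothing).

    Returns the surrogate state matrix on the grid and the spline objects
    (whose coefficients are the interpolant parameters of the objective).
    """
    t = np.asarray(t, float)
    splines = []
    Xhat = np.empty_like(Y, dtype=float)
    for s in range(Y.shape[0]):
        spl = interpolate.make_smoothing_spline(t, Y[s])  # GCV lambda
        splines.append(spl)
        Xhat[s] = spl(t)
    return Xhat, splines


def _structural_zero_deltas(model: ODEModel) -> np.ndarray:
    """Species whose decay rate is identically zero for any theta."""
    probe = np.ones(model.n_params)
    return np.asarray(model.deltas(probe), float) == 0.0


def _effective_split(model: ODEModel, Xhat: np.ndarray, theta: np.ndarray,
                     floor: float):
    """(g, delta) per species, flooring only structurally zero decay rates.

    Species with an identically-zero decay rate get the grid floor (their
    R = D would otherwise be singular for every theta), with the deficit
    moved into g at the surrogate.  Theta-dependent decay rates are used as
    they are: if the optimiser drives one towards zero the ridge system
    becomes ill-conditioned and the lambda is rejected, which is the
    documented failure mode of the AIC selection path on the pathway model.
    """
    G = np.asarray(model.g(Xhat, theta, None))
    deltas = np.asarray(model.deltas(theta), float)
    eff = np.where(_structural_zero_deltas(model), floor, deltas)
    G = G + (eff - deltas)[:, None] * Xhat
    return G, eff


def penalized_loglik(theta: np.ndarray, model: ODEModel, t: np.ndarray,
                     Y: np.ndarray, Xhat: np.ndarray, lam: float | np.ndarray,
                     sigma2: np.ndarray, diff: DiffOperator | None = None,
                     return_parts: bool = False):
    """Penalised log-likelihood (fit term minus lambda-weighted RKHS norms).

    ``Xhat`` is the spline surrogate fed into g_s (the linearisation);
    ``sigma2`` the per-species observation variances defining Sigma.
    """
    diff = build_D(t) if diff is None else diff
    theta = np.asarray(theta, float)
    lam_vec = np.broadcast_to(np.atleast_1d(np.asarray(lam, float)), (Y.shape[0],))
    G, deltas = _effective_split(model, Xhat, theta, diff.delta_floor)
    fit_term = 0.0
    penalty = 0.0
    T = len(t)
    for s in range(Y.shape[0]):
        problem = RKHSProblem.build(diff, float(deltas[s]), float(sigma2[s]),
                                    float(lam_vec[s]))
        y_tilde = transform(problem, Y[s], G[s])
        x_tilde = solve_xtilde(problem, y_tilde)
        resid = y_tilde - x_tilde
        fit_term += float(-0.5 * resid @ resid / sigma2[s]
                          - 0.5 * T * math.log(sigma2[s]))
        penalty += lam_vec[s] * penalty_omega(problem, x_tilde)
    value = fit_term - penalty
    if return_parts:
        return value, fit_term, penalty
    return value


@dataclass
class RKHSFit:
    theta: np.ndarray
    lambda_s: float | np.ndarray
    objective: float
    fit_term: float
    n_restarts_ok: int
    converged: bool
    spline_coeffs: list | None = None
    param_names: tuple[str, ...] = ()
    n_rejected_events: int = 0   # singular ridge systems hit while optimising
    sigma2: np.ndarray | None = None   # estimated noise variances, if inferred


def _make_objective(model, t, Y, Xhat, lam, sigma2, diff):
    """Negative penalised log-likelihood over theta at fixed Sigma."""
    positive = model.positive_params
    P = model.n_params

    def z_to_theta(z):
        th = np.array(z[:P], float)
        for k, pos in enumerate(positive):
            if pos:
                th[k] = math.exp(min(z[k], 60.0))
        return th

    def neg(z):
        # singular ridge systems act as a wall during the search; a restart
        # is rejected only if the optimiser converges inside one
        if np.any(np.abs(z) > 60):
            return 1e12
        theta = z_to_theta(z)
        try:
            val = penalized_loglik(theta, model, t, Y, Xhat, lam, sigma2,
                                   diff)
        except (RejectedLambda, linalg.LinAlgError, FloatingPointError):
            return 1e12
        return 1e12 if not np.isfinite(val) else -val

    return neg, z_to_theta


def fit(dataset_or_data, model: ODEModel, lam: float | np.ndarray,
        sigma2: np.ndarray | None = None, n_restarts: int = 5, seed: int = 0,
        priors: PriorSet | None = None, Xhat: np.ndarray | None = None,
        t: np.ndarray | None = None, Y: np.ndarray | None = None) -> RKHSFit:
    """Maximise the penalised likelihood over theta at fixed lambda.

    Multi-start quasi-Newton (L-BFGS-B) on a log scale for positivity-
    constrained parameters; restart points drawn from the model's priors.
    """
    if isinstance(dataset_or_data, Dataset):
        ds = dataset_or_data
        t = ds.t if t is None else t
        Y = ds.Y if Y is None else Y
        if sigma2 is None:
            sigma2 = np.asarray(ds.realized_sd, float) ** 2
    if t is None or Y is None:
        raise ValueError("need (t, Y) either via a Dataset or explicitly")
    infer_sigma = isinstance(sigma2, str) and sigma2 == "infer"
    priors = default_priors(model.name) if priors is None else priors
    rng = np.random.default_rng(seed)
    splines = None
    if Xhat is None:
        Xhat, splines = fit_surrogate(t, Y)
    if infer_sigma:
        # noise variances from the smoothing-spline surrogate residuals
        # (joint sigma-MLE of the penalised likelihood is degenerate:
        # sigma -> 0 sends it to +inf)
        T = Y.shape[1]
        sigma2_arr = np.maximum(((Y - Xhat) ** 2).sum(axis=1)
                                / max(T - 4, 1), 1e-10)
    else:
        sigma2_arr = np.asarray(sigma2, float)
    diff = build_D(t)
    neg, z_to_theta = _make_objective(model, t, Y, Xhat, lam, sigma2_arr, diff)

    best = None
    n_ok = 0
    n_rejected = 0
    last_err: Exception | None = None
    for k in range(n_restarts):
        theta0 = np.abs(priors.sample_theta(rng)) + 1e-3
        z0 = np.array([math.log(v) if pos else v
                       for v, pos in zip(theta0, model.positive_params)])
        res = optimize.minimize(neg, z0, method="L-BFGS-B")
        if not np.isfinite(res.fun) or res.fun >= 1e11:
            n_rejected += 1
            last_err = RejectedLambda(
                f"optimiser converged inside a singular region at lambda={lam}")
            continue
        try:
            # re-evaluate at the converged point: if the ridge system is
            # singular there, this restart chose inadmissible parameters
            penalized_loglik(z_to_theta(res.x), model, t, Y, Xhat, lam,
                             sigma2_arr, diff)
        except (RejectedLambda, linalg.LinAlgError) as exc:
            n_rejected += 1
            last_err = exc if isinstance(exc, RejectedLambda) else \
                RejectedLambda(str(exc))
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        if last_err is not None:
            raise last_err
        raise RuntimeError("all optimisation restarts failed")
    theta_hat = z_to_theta(best.x)
    obj, fit_term, _pen = penalized_loglik(theta_hat, model, t, Y, Xhat, lam,
                                           sigma2_arr, diff, return_parts=True)
    return RKHSFit(theta=theta_hat, lambda_s=lam, objective=float(obj),
                   fit_term=float(fit_term), n_restarts_ok=n_ok,
                   converged=bool(best.success), spline_coeffs=splines,
                   param_names=model.params, n_rejected_events=n_rejected,
                   sigma2=sigma2_arr if infer_sigma else None)


def _effective_dof(dataset: Dataset, model: ODEModel, theta: np.ndarray,
                   lam: float, sigma2: np.ndarray) -> float:
    """Trace of the ridge smoother K(K + 2 lambda Sigma)^{-1}, summed over
    species: the effective number of state degrees of freedom at lambda."""
    diff = build_D(dataset.t)
    deltas = np.where(_structural_zero_deltas(model), diff.delta_floor,
                      np.asarray(model.deltas(theta), float))
    dof = 0.0
    for s in range(dataset.Y.shape[0]):
        problem = RKHSProblem.build(diff, float(deltas[s]), float(sigma2[s]),
                                    float(lam))
        # smoother trace in the primal form: tr[(Sinv + 2 lam R'R)^-1 Sinv]
        Sinv = np.diag(1.0 / np.diag(problem.Sigma))
        Msys = Sinv + 2.0 * lam * (problem.R.T @ problem.R)
        if np.linalg.cond(Msys) > _COND_MAX:
            raise RejectedLambda(f"singular ridge system at lambda={lam}")
        dof += float(np.trace(linalg.solve(Msys, Sinv, assume_a="sym")))
    return dof


def select_lambda_aic(dataset: Dataset, model: ODEModel,
                      lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
                      sigma2: np.ndarray | None = None, n_restarts: int = 3,
                      seed: int = 0) -> tuple[float, RKHSFit, dict]:
    """Choose lambda minimising AIC = 2k - 2 * (maximised fit term).

    k counts the estimated ODE parameters plus the effective degrees of
    freedom of the ridge smoother (the trace of K(K + 2 lambda Sigma)^{-1}
    summed over species).  Counting the smoother is essential: the fit term
    alone is monotone in lambda, so a fixed k would always select the
    smallest value on the grid.  Lambdas whose ridge system is singular are
    skipped; if all are rejected an error recommends the CV route.
    """
    lambda_grid = np.atleast_1d(np.asarray(lambda_grid, float))
    if len(lambda_grid) < 1:
        raise ValueError("lambda grid is empty")
    infer_sigma = isinstance(sigma2, str) and sigma2 == "infer"
    if sigma2 is None:
        sigma2 = np.asarray(dataset.realized_sd, float) ** 2
    scores: dict[float, float] = {}
    fits: dict[float, RKHSFit] = {}
    rejected = []
    events = 0
    for lam in lambda_grid:
        try:
            f = fit(dataset, model, float(lam), sigma2=sigma2,
                    n_restarts=n_restarts, seed=seed)
            sig_dof = f.sigma2 if infer_sigma else sigma2
            k = model.n_params + _effective_dof(dataset, model, f.theta,
                                               float(lam), sig_dof)
        except (RejectedLambda, RuntimeError):
            rejected.append(float(lam))
            events += 1
            continue
        events += f.n_rejected_events
        scores[float(lam)] = 2.0 * k - 2.0 * f.fit_term
        fits[float(lam)] = f
    if not scores:
        raise RejectedLambda(
            "every lambda in the grid was rejected (singular ridge system); "
            "try cross-validation selection instead")
    lam_star = min(scores, key=scores.get)
    info = {"aic": scores, "rejected": rejected, "rejection_events": events}
    return lam_star, fits[lam_star], info


def _interleaved_folds(T: int, n_folds: int = 3):
    return [np.arange(T)[f::n_folds] for f in range(n_folds)]


def _cv_predict(model: ODEModel, theta: np.ndarray, t: np.ndarray,
                Y: np.ndarray, Xhat: np.ndarray, lam: float,
                sigma2: np.ndarray, train: np.ndarray, test: np.ndarray) -> float:
    """Held-out SSE of the back-transformed reconstructed states.

    The difference operator lives on the full grid; the ridge problem is
    solved with zero weight on held-out rows (the missing-data form of the
    same estimator), and the reconstructed states are scored against the
    held-out observations.  An unregularised system (small lambda leaves
    the unobserved rows unconstrained) raises :class:`RejectedLambda`.
    """
    diff = build_D(t)
    G, deltas = _effective_split(model, Xhat, theta, diff.delta_floor)
    T = len(t)
    w = np.zeros(T)
    w[train] = 1.0
    sse = 0.0
    for s in range(Y.shape[0]):
        problem = RKHSProblem.build(diff, float(deltas[s]), float(sigma2[s]), lam)
        shift = linalg.solve(problem.R, G[s])
        y_tilde = (Y[s] - shift) * w          # held-out rows get zero weight
        Msys = (np.diag(w / sigma2[s])
                + 2.0 * lam * (problem.R.T @ problem.R))
        if np.linalg.cond(Msys) > _COND_MAX:
            raise RejectedLambda(f"singular CV ridge system at lambda={lam}")
        x_tilde = linalg.solve(Msys, y_tilde / sigma2[s], assume_a="sym")
        x_test = x_tilde[test] + shift[test]
        sse += float(((Y[s][test] - x_test) ** 2).sum())
    return sse


def select_lambda_cv(dataset: Dataset, model: ODEModel,
                     lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
                     sigma2: np.ndarray | None = None, n_folds: int = 3,
                     n_restarts: int = 3, seed: int = 0
                     ) -> tuple[float, RKHSFit, dict]:
    """Threefold cross-validated lambda selection (interleaved folds).

    For each lambda: fit theta on two folds, score the predictive SSE of
    the reconstructed states on the held-out fold, average; pick the
    argmin and refit on all data.  Lambdas raising singular systems in any
    fold are rejected and skipped.
    """
    t, Y = dataset.t, dataset.Y
    T = len(t)
    if T < 2 * n_folds:
        raise ValueError("too few timepoints for cross-validation")
    infer_sigma = isinstance(sigma2, str) and sigma2 == "infer"
    if sigma2 is None:
        sigma2 = np.asarray(dataset.realized_sd, float) ** 2
    lambda_grid = np.atleast_1d(np.asarray(lambda_grid, float))
    folds = _interleaved_folds(T, n_folds)
    all_idx = np.arange(T)
    # per-fold surrogate fitted on training data only, evaluated on the
    # full grid (used both for fitting and for held-out prediction)
    fold_surrogates = []
    for test in folds:
        train = np.setdiff1d(all_idx, test)
        _, spls = fit_surrogate(t[train], Y[:, train])
        fold_surrogates.append(np.array([spl(t) for spl in spls]))
    scores: dict[float, float] = {}
    rejected = []
    events = 0
    for lam in lambda_grid:
        fold_scores = []
        try:
            for f, test in enumerate(folds):
                train = np.setdiff1d(all_idx, test)
                Xhat_f = fold_surrogates[f]
                f_train = fit(dataset, model, float(lam), sigma2=sigma2,
                              n_restarts=n_restarts, seed=seed + 17 * f,
                              Xhat=Xhat_f[:, train], t=t[train], Y=Y[:, train])
                events += f_train.n_rejected_events
                sig_pred = f_train.sigma2 if infer_sigma else sigma2
                fold_scores.append(_cv_predict(model, f_train.theta, t, Y,
                                               Xhat_f, float(lam), sig_pred,
                                               train, test))
        except (RejectedLambda, RuntimeError):
            rejected.append(float(lam))
            events += 1
            continue
        scores[float(lam)] = float(np.mean(fold_scores))
    if not scores:
        raise RejectedLambda("every lambda was rejected in cross-validation")
    lam_star = min(scores, key=scores.get)
    final = fit(dataset, model, lam_star, sigma2=sigma2,
                n_restarts=n_restarts, seed=seed)
    info = {"cv_sse": scores, "rejected": rejected, "rejection_events": events}
    return lam_star, final, info
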