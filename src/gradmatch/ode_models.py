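"""Benchmark ODE systems for gradient-matching inference.

Two systems are registered:

* The FitzHugh--Nagumo oscillator: two species, voltage ``V`` and recovery
  variable ``R``, three kinetic parameters ``(alpha, beta, psi)``.  Produces
  periodic relaxation oscillations.
* A protein signalling transduction pathway: five species ``(S, dS, R, RS,
  Rpp)``, six parameters ``(k1, k2, k3, k4, V, Km)``; mass-action kinetics
  plus one Michaelis--Menten term.  The signal rises and settles into a
  stationary phase.

Each model carries, besides the plain right-hand side ``f_s(x, theta, t)``,
a *decay decomposition* ``f_s = g_s(x, theta, t) - delta_s * x_s`` that
separates a linear self-degradation rate ``delta_s`` from the remaining
kinetics ``g_s``.  The RKHS penalised-likelihood estimator operates on this
form; the decomposition is model-supplied because it is not unique (for
FitzHugh--Nagumo the recovery equation's decay rate is beta/psi, entangling
delta with the kinetic parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the parameter vector."""

    def __init__(self, message: str, theta: np.ndarray):
        super().__init__(f"{message} (theta={np.asarray(theta).tolist()})")
        self.theta = np.asarray(theta, dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """A noiseless solution of an ODE system sampled on a time grid."""

    t: np.ndarray          # (T,) strictly increasing
    X: np.ndarray          # (N, T) species x time
    theta_true: np.ndarray
    x0: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be 1-d and strictly increasing")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("trajectory contains non-finite values")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))


@dataclass(frozen=True)
class ODEModel:
    """An ODE system f_s(x, theta, t) with its decay decomposition.

    ``rhs(x, theta, t)`` maps a state vector (or an (N, T) state matrix,
    vectorised over columns) and parameter vector to derivatives of the same
    shape.  ``g(x, theta, t)`` and ``deltas(theta)`` satisfy
    ``rhs == g - deltas[:, None] * x`` identically.
    """

    name: str
    species: tuple[str, ...]
    params: tuple[str, ...]
    rhs: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    g: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    deltas: Callable[[np.ndarray], np.ndarray]
    positive_params: tuple[bool, ...] = field(default=None)  # type: ignore[assignment]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_params(self) -> int:
        return len(self.params)


def fhn_rhs(state: np.ndarray, params: Sequence[float], t: float = 0.0) -> np.ndarray:
    """FitzHugh--Nagumo derivatives.

    dV/dt = psi * (V - V^3/3 + R)
    dR/dt = -(1/psi) * (V - alpha + beta * R)
    """
    alpha, beta, psi = params
    if psi == 0:
        raise ZeroDivisionError("FitzHugh-Nagumo rate psi must be nonzero")
    state = np.asarray(state, dtype=float)
    V, R = state[0], state[1]
    dV = psi * (V - V**3 / 3.0 + R)
    dR = -(V - alpha + beta * R) / psi
    return np.stack([dV, dR])


def _fhn_g(state: np.ndarray, params: Sequence[float], t: float = 0.0) -> np.ndarray:
    alpha, beta, psi = params
    state = np.asarray(state, dtype=float)
    V, R = state[0], state[1]
    gV = psi * (V - V**3 / 3.0 + R)          # no linear self-decay in V
    gR = -(V - alpha) / psi                   # decay rate beta/psi split off
    return np.stack([gV, gR])


def _fhn_deltas(params: Sequence[float]) -> np.ndarray:
    alpha, beta, psi = params
    return np.array([0.0, beta / psi])


def ptp_rhs(state: np.ndarray, params: Sequence[float], t: float = 0.0) -> np.ndarray:
    """Protein signalling transduction pathway derivatives.

    S + R <-> RS -> Rpp + S with enzyme degradation S -> dS and
    Michaelis-Menten dephosphorylation Rpp -> R.
    """
    k1, k2, k3, k4, V, Km = params
    state = np.asarray(state, dtype=float)
    S, dS, R, RS, Rpp = state
    if np.any(Km + Rpp == 0):
        raise ZeroDivisionError("Km + [Rpp] must be nonzero in the Michaelis-Menten term")
    mm = V * Rpp / (Km + Rpp)
    dS_dt = -k1 * S - k2 * S * R + k3 * RS
    ddS_dt = k1 * S
    dR_dt = -k2 * S * R + k3 * RS + mm
    dRS_dt = k2 * S * R - k3 * RS - k4 * RS
    dRpp_dt = k4 * RS - mm
    return np.stack([dS_dt, ddS_dt, dR_dt, dRS_dt, dRpp_dt])


def _ptp_g(state: np.ndarray, params: Sequence[float], t: float = 0.0) -> np.ndarray:
    k1, k2, k3, k4, V, Km = params
    state = np.asarray(state, dtype=float)
    S, dS, R, RS, Rpp = state
    mm = V * Rpp / (Km + Rpp)
    zeros = np.zeros(np.shape(S))
    gS = -k2 * S * R + k3 * RS            # delta_S = k1
    gdS = k1 * S + zeros
    gR = -k2 * S * R + k3 * RS + mm
    gRS = k2 * S * R - k3 * RS            # delta_RS = k4
    gRpp = k4 * RS - mm
    return np.stack([gS, gdS, gR, gRS, gRpp])


def _ptp_deltas(params: Sequence[float]) -> np.ndarray:
    k1, k2, k3, k4, V, Km = params
    return np.array([k1, 0.0, 0.0, k4, 0.0])


FHN = ODEModel(
    name="fhn",
    species=("V", "R"),
    params=("alpha", "beta", "psi"),
    rhs=fhn_rhs,
    g=_fhn_g,
    deltas=_fhn_deltas,
    positive_params=(False, False, True),
)

PTP = ODEModel(
    name="ptp",
    species=("S", "dS", "R", "RS", "Rpp"),
    params=("k1", "k2", "k3", "k4", "V", "Km"),
    rhs=ptp_rhs,
    g=_ptp_g,
    deltas=_ptp_deltas,
    positive_params=(True,) * 6,
)

MODELS: dict[str, ODEModel] = {"fhn": FHN, "ptp": PTP}


def get_model(name: str) -> ODEModel:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(MODELS)}") from None


def solve(model: ODEModel, theta: Sequence[float], x0: Sequence[float],
          t: np.ndarray, rtol: float = 1e-8, atol: float = 1e-8) -> Trajectory:
    """Integrate the model with an adaptive Runge-Kutta scheme, sampled at t.

    Both benchmark systems are non-stiff at their standard parameters, so an
    explicit RK45 with tight tolerances suffices.
    """
    t = np.asarray(t, dtype=float)
    theta = np.asarray(theta, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    sol = solve_ivp(
        lambda tt, xx: model.rhs(xx, theta, tt),
        (t[0], t[-1]), x0, t_eval=t, method="RK45", rtol=rtol, atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"integration of {model.name} failed: {sol.message}", theta)
    return Trajectory(t=t, X=sol.y, theta_true=theta, x0=x0)
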