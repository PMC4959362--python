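"""Synthetic time-course data for the benchmark study regimes.

All test inputs are produced here: the ODE is solved numerically at the
generating parameters and corrupted with one of three noise models,

* ``additive_fixed_sd`` -- y_s(t) = x_s(t) + eps, eps ~ N(0, sd_s^2), a
  per-species standard deviation;
* ``multiplicative``    -- y_s(t) = x_s(t) * (1 + eps), eps ~ N(0, sd^2);
* ``additive_snr``      -- additive with a single shared sd chosen so that
  the *average* signal-to-noise ratio over species hits a target, where
  SNR_s = sd(noiseless signal of species s) / noise sd.  A shared sd means
  every species has the same observational error.

Standard regimes (generating parameters, grids and noise levels of the two
benchmark studies) are registered in :data:`REGIMES`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ode_models import MODELS, ODEModel, Trajectory, solve

NOISE_KINDS = ("additive_fixed_sd", "multiplicative", "additive_snr")


@dataclass(frozen=True)
class NoiseSpec:
    kind: str
    sd: float | Sequence[float]   # per-species sds, scalar sd, or SNR target
    seed: int = 0

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {NOISE_KINDS}")
        sd = np.atleast_1d(np.asarray(self.sd, dtype=float))
        if np.any(sd <= 0):
            raise ValueError("noise sd / SNR target must be positive")


@dataclass(frozen=True)
class Dataset:
    """Noisy observations plus the generating truth, for evaluation."""

    t: np.ndarray
    Y: np.ndarray                 # (N, T)
    truth: Trajectory
    noise: NoiseSpec
    realized_sd: np.ndarray       # per-species sd actually applied

    def __post_init__(self):
        if self.Y.shape != self.truth.X.shape:
            raise ValueError("Y and truth.X shapes disagree")


def sd_from_snr(trajectory: Trajectory, snr: float) -> float:
    """Shared noise sd such that mean_s[ sd(signal_s)/sd ] equals ``snr``."""
    if snr <= 0:
        raise ValueError("SNR target must be positive")
    signal_sd = trajectory.X.std(axis=1, ddof=1)
    if np.all(signal_sd == 0):
        raise ValueError("SNR undefined for an all-constant trajectory")
    return float(signal_sd.mean() / snr)


def generate(model: ODEModel, theta: Sequence[float], x0: Sequence[float],
             t: np.ndarray, noise: NoiseSpec) -> Dataset:
    """Solve the ODE at ``theta`` and corrupt it per the noise spec."""
    truth = solve(model, theta, x0, t)
    rng = np.random.default_rng(noise.seed)
    N, T = truth.X.shape
    if noise.kind == "additive_fixed_sd":
        sd = np.broadcast_to(np.atleast_1d(np.asarray(noise.sd, float)), (N,)).copy()
        if np.atleast_1d(np.asarray(noise.sd)).size not in (1, N):
            raise ValueError("sd vector length must be 1 or n_species")
        Y = truth.X + sd[:, None] * rng.standard_normal((N, T))
    elif noise.kind == "multiplicative":
        sd_scalar = float(np.atleast_1d(np.asarray(noise.sd, float))[0])
        Y = truth.X * (1.0 + sd_scalar * rng.standard_normal((N, T)))
        # effective additive sd varies with the signal level; report |x|*sd
        sd = np.abs(truth.X).mean(axis=1) * sd_scalar
    else:  # additive_snr
        snr = float(np.atleast_1d(np.asarray(noise.sd, float))[0])
        shared = sd_from_snr(truth, snr)
        sd = np.full(N, shared)
        Y = truth.X + shared * rng.standard_normal((N, T))
    return Dataset(t=truth.t, Y=Y, truth=truth, noise=noise, realized_sd=sd)


# ---------------------------------------------------------------------------
# Benchmark regimes

FHN_THETA = np.array([0.2, 0.2, 3.0])
FHN_X0 = np.array([-1.0, 1.0])
FHN_X0_GON = np.array([-1.0, -1.0])
PTP_THETA = np.array([0.07, 0.6, 0.05, 0.3, 0.017, 0.3])
PTP_X0 = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
PTP_GRID = np.array([0, 1, 2, 4, 5, 7, 10, 15, 20, 30, 40, 50, 60, 80, 100.0])


def regime_dataset(name: str, seed: int = 0, snr: float | None = None) -> Dataset:
    """Generate a dataset from one of the named benchmark regimes.

    ``fhn_cs_401``  401 obs on [0, 20] (two periods), additive sd (0.5, 0.4)
    ``fhn_cs_20``   20 obs on [0, 10] (one period), additive sd (0.5, 0.4)
    ``fhn_gon_50``  50 obs on [0, 20], x0 = (-1, -1), additive sd 0.1
    ``fhn_snr``     25 obs on [0, 10], additive at average SNR (default 10)
    ``ptp_inf``     15-point grid to t=100, multiplicative sd 0.1
    ``ptp_snr``     15-point grid, additive at average SNR (default 10)
    """
    snr = 10.0 if snr is None else snr
    if name == "fhn_cs_401":
        return generate(MODELS["fhn"], FHN_THETA, FHN_X0, np.linspace(0, 20, 401),
                        NoiseSpec("additive_fixed_sd", (0.5, 0.4), seed))
    if name == "fhn_cs_20":
        return generate(MODELS["fhn"], FHN_THETA, FHN_X0, np.linspace(0, 10, 20),
                        NoiseSpec("additive_fixed_sd", (0.5, 0.4), seed))
    if name == "fhn_gon_50":
        return generate(MODELS["fhn"], FHN_THETA, FHN_X0_GON, np.linspace(0, 20, 50),
                        NoiseSpec("additive_fixed_sd", 0.1, seed))
    if name == "fhn_snr":
        return generate(MODELS["fhn"], FHN_THETA, FHN_X0, np.linspace(0, 10, 25),
                        NoiseSpec("additive_snr", snr, seed))
    if name == "ptp_inf":
        return generate(MODELS["ptp"], PTP_THETA, PTP_X0, PTP_GRID,
                        NoiseSpec("multiplicative", 0.1, seed))
    if name == "ptp_snr":
        return generate(MODELS["ptp"], PTP_THETA, PTP_X0, PTP_GRID,
                        NoiseSpec("additive_snr", snr, seed))
    raise ValueError(f"unknown regime {name!r}")


REGIMES = ("fhn_cs_401", "fhn_cs_20", "fhn_gon_50", "fhn_snr", "ptp_inf", "ptp_snr")


# ---------------------------------------------------------------------------
# Serialization: CSV with a time column + one column per species, JSON sidecar

def dataset_to_csv(ds: Dataset, path: str | Path, model: ODEModel | None = None) -> None:
    path = Path(path)
    species = model.species if model is not None else [f"x{i}" for i in range(ds.Y.shape[0])]
    frame = pd.DataFrame({"time": ds.t})
    for i, name in enumerate(species):
        frame[name] = ds.Y[i]
    frame.to_csv(path, index=False)
    sidecar = {
        "theta_true": ds.truth.theta_true.tolist(),
        "x0": ds.truth.x0.tolist(),
        "noise": {"kind": ds.noise.kind,
                  "sd": np.atleast_1d(np.asarray(ds.noise.sd, float)).tolist(),
                  "seed": ds.noise.seed},
        "realized_sd": ds.realized_sd.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_observations(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a (time, species...) CSV; returns (t, Y with species rows, names)."""
    frame = pd.read_csv(path)
    if "time" not in frame.columns:
        raise ValueError("observation CSV must have a 'time' column")
    names = [c for c in frame.columns if c != "time"]
    return frame["time"].to_numpy(float), frame[names].to_numpy(float).T, names
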