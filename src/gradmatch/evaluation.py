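"""Comparison metrics for the benchmark study.

Point estimates are posterior medians (a robust average); estimators are
compared through absolute parameter errors |theta_hat - theta|, through
the RMS discrepancy in function space (the ODE is integrated at the
estimate and the noiseless true signal subtracted), through ECDFs of the
absolute errors with one-sided two-sample Kolmogorov-Smirnov tests (a
significantly higher ECDF of errors means better estimation), and by
selecting the replicate dataset with median parameter-sample RMS for
display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ode_models import IntegrationError, ODEModel, Trajectory, solve


def point_estimate(samples: np.ndarray) -> np.ndarray:
    """Componentwise median of an (n_samples, P) array."""
    samples = np.asarray(samples, float)
    if samples.size == 0:
        raise ValueError("no samples")
    return np.median(samples, axis=0)


def absolute_errors(estimates: np.ndarray, truth: np.ndarray) -> np.ndarray:
    return np.abs(np.asarray(estimates, float) - np.asarray(truth, float))


def rms_function_space(theta_hat: np.ndarray, model: ODEModel,
                       truth: Trajectory, t_dense: np.ndarray | None = None) -> float:
    """RMS of (reconstructed - true) signals over species and timepoints.

    The ODE is integrated at ``theta_hat`` from the true initial values on
    the observation grid (configurable via ``t_dense``).
    """
    t = truth.t if t_dense is None else np.asarray(t_dense, float)
    X_true = truth.X if t_dense is None else solve(model, truth.theta_true,
                                                   truth.x0, t).X
    X_hat = solve(model, theta_hat, truth.x0, t).X
    return float(np.sqrt(np.mean((X_hat - X_true) ** 2)))


def rms_function_space_samples(theta_samples: np.ndarray, model: ODEModel,
                               truth: Trajectory) -> tuple[np.ndarray, int]:
    """Per-sample function-space RMS; integration failures are skipped."""
    values = []
    skipped = 0
    for theta in np.asarray(theta_samples, float):
        try:
            values.append(rms_function_space(theta, model, truth))
        except IntegrationError:
            skipped += 1
    return np.array(values), skipped


def ecdf(values: np.ndarray):
    """Empirical CDF as (sorted values, cumulative fractions)."""
    v = np.sort(np.asarray(values, float))
    return v, np.arange(1, len(v) + 1) / len(v)


@dataclass(frozen=True)
class KSComparison:
    p_a_above_b: float     # test of "A's error ECDF lies above B's"
    p_b_above_a: float
    statistic_a_above_b: float
    significant_a_above_b: bool
    significant_b_above_a: bool


def ecdf_ks(errors_a: np.ndarray, errors_b: np.ndarray,
            level: float = 0.05) -> KSComparison:
    """One-sided two-sample KS tests between two absolute-error samples.

    "A above B" means A's ECDF is higher, i.e. A's errors are
    stochastically smaller: better estimation by method A.
    """
    a = np.asarray(errors_a, float)
    b = np.asarray(errors_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    # scipy alternative='greater': small p-value when the first sample's
    # ECDF lies above the second's (its errors are stochastically smaller)
    res_ab = stats.ks_2samp(a, b, alternative="greater")
    res_ba = stats.ks_2samp(a, b, alternative="less")
    return KSComparison(
        p_a_above_b=float(res_ab.pvalue),
        p_b_above_a=float(res_ba.pvalue),
        statistic_a_above_b=float(res_ab.statistic),
        significant_a_above_b=bool(res_ab.pvalue < level),
        significant_b_above_a=bool(res_ba.pvalue < level),
    )


def median_dataset(samples_per_dataset, truth: np.ndarray) -> int:
    """Index of the replicate with median RMS of (samples - truth).

    The RMS is over all retained samples and parameters; with an even
    count the lower median is taken.
    """
    truth = np.asarray(truth, float)
    if len(samples_per_dataset) == 0:
        raise ValueError("no datasets")
    rms = np.array([
        float(np.sqrt(np.mean((np.asarray(s, float) - truth) ** 2)))
        for s in samples_per_dataset
    ])
    order = np.argsort(rms, kind="stable")
    return int(order[(len(rms) - 1) // 2])
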