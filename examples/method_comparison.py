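"""Comparing estimators with the benchmark's own metrics.

Runs a miniature experiment (one replicate of the pathway regime, the
base-2 tempered sampler vs the threefold-CV RKHS estimator at a small
budget), then evaluates absolute parameter errors, the function-space RMS
of the reconstructed signals, and a one-sided Kolmogorov-Smirnov
comparison of the two error distributions.
"""

import numpy as np

from gradmatch import PTP, regime_dataset, run_sampler, select_lambda_cv
from gradmatch.evaluation import (absolute_errors, ecdf_ks, point_estimate,
                                  rms_function_space)

dataset = regime_dataset("ptp_snr", seed=202, snr=10)
truth = dataset.truth.theta_true

sampler_out = run_sampler(dataset, PTP, mode="lb2", chains=4,
                          iterations=4000, burn_in=2000, thin=10, seed=2,
                          fix_sigma=True)
theta_mcmc = point_estimate(sampler_out.theta_target)

_, rkhs_fit, _ = select_lambda_cv(dataset, PTP, sigma2=dataset.realized_sd**2,
                                  n_restarts=3, seed=2)
theta_rkhs = rkhs_fit.theta

err_mcmc = absolute_errors(theta_mcmc, truth)
err_rkhs = absolute_errors(theta_rkhs, truth)
print(f"{'parameter':>10s} {'truth':>7s} {'lb2':>7s} {'gon_cv':>7s}")
for p, name in enumerate(PTP.params):
    print(f"{name:>10s} {truth[p]:7.3f} {theta_mcmc[p]:7.3f} {theta_rkhs[p]:7.3f}")

rms_mcmc = rms_function_space(theta_mcmc, PTP, dataset.truth)
rms_rkhs = rms_function_space(theta_rkhs, PTP, dataset.truth)
print(f"function-space RMS: lb2 {rms_mcmc:.4f}  gon_cv {rms_rkhs:.4f}")
print("(the ODE is re-integrated at each estimate and compared with the "
      "noiseless truth: small RMS can coexist with large errors on weakly "
      "identified parameters such as V and Km)")

ks = ecdf_ks(err_mcmc, err_rkhs)
print(f"one-sided KS: p(lb2 errors stochastically smaller) = "
      f"{ks.p_a_above_b:.3f}, p(gon_cv smaller) = {ks.p_b_above_a:.3f}")
print("at a single replicate and six parameters neither direction reaches "
      "significance; the benchmark pools replicates for this comparison")
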