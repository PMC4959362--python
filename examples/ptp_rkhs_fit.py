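"""RKHS penalised-likelihood fit of the protein signalling pathway.

Generates the 15-timepoint pathway dataset at average signal-to-noise
ratio 10, selects the penalty parameter lambda by threefold cross-
validation over a log-spaced grid, and prints the resulting estimates of
the six kinetic parameters.  The estimator never integrates the ODE: time
differentiation is approximated by a difference operator, the non-linear
kinetics are linearised on a smoothing-spline surrogate, and the states
solve a closed-form ridge problem.
"""

import numpy as np

from gradmatch import PTP, regime_dataset, select_lambda_cv

dataset = regime_dataset("ptp_snr", seed=201, snr=10)
print(f"data: {dataset.Y.shape[1]} timepoints, {dataset.Y.shape[0]} species, "
      f"shared noise sd {dataset.realized_sd[0]:.4f}")

lam, fit, info = select_lambda_cv(dataset, PTP,
                                  sigma2=dataset.realized_sd**2,
                                  n_restarts=3, seed=1)
print(f"selected lambda  : {lam:g} "
      f"({len(info['rejected'])} grid values rejected as singular)")
print(f"{'parameter':>10s} {'truth':>8s} {'estimate':>9s}")
for name, tru, est in zip(PTP.params, dataset.truth.theta_true, fit.theta):
    print(f"{name:>10s} {tru:8.3f} {est:9.3f}")
print("k1 and k4 are recovered closely; k2 carries the difference-operator "
      "truncation bias of the method on this irregular grid, and k3 (whose "
      "kinetic term lies below the noise floor) and the Michaelis-Menten "
      "pair (V, Km), of which only the ratio is identified, are weakly "
      "determined - the known behaviour of this estimator at this noise "
      "level")
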