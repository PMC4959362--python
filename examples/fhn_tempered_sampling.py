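"""Tempered gradient-matching inference on the FitzHugh-Nagumo oscillator.

Generates the reduced benchmark dataset (20 noisy observations of voltage
and recovery over one period), runs the base-10 tempered sampler with a
4-chain ladder at a small sweep budget, and prints the posterior medians
of the three kinetic parameters next to the values that generated the
data.  The mismatch variance gamma is fixed per chain (1, 0.1, 0.01,
0.001): the coldest chain forces the GP interpolant's slopes to agree
with the ODE gradients, and between-chain swaps let it escape local modes.
"""

import numpy as np

from gradmatch import FHN, regime_dataset, run_sampler
from gradmatch.evaluation import absolute_errors, point_estimate

dataset = regime_dataset("fhn_cs_20", seed=101)
print(f"data: {dataset.Y.shape[1]} observations of {dataset.Y.shape[0]} "
      f"species, noise sd {dataset.realized_sd}")

out = run_sampler(dataset, FHN, mode="lb10", chains=4, iterations=8000,
                  burn_in=4000, thin=10, seed=1, fix_sigma=True,
                  sample_eta=False)

median = point_estimate(out.theta_target)
errors = absolute_errors(median, dataset.truth.theta_true)
print(f"retained samples : {out.n_samples}")
print(f"swap acceptance  : {out.swap_accept_rate:.2f}")
print(f"{'parameter':>10s} {'truth':>8s} {'median':>8s} {'abs err':>8s}")
for name, tru, med, err in zip(FHN.params, dataset.truth.theta_true,
                               median, errors):
    print(f"{name:>10s} {tru:8.3f} {med:8.3f} {err:8.3f}")
print("the medians are the sampler's point estimates; at this noise level "
      "(sd 0.5/0.4 on a signal of amplitude ~2) and 20 points, alpha is "
      "recovered well while beta and psi carry the attenuation typical of "
      "gradient matching on sparse data")
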