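# gradmatch

Approximate parameter inference for biological-pathway ODE models by
**gradient matching**: instead of re-integrating the system at every
candidate parameter vector, an interpolant is fitted to the noisy time
courses and the kinetic parameters are scored by how well the
ODE-predicted derivatives `f_s(x, theta, t)` match the interpolant's
slopes.  The package implements and compares two estimators on two
benchmark systems (the FitzHugh–Nagumo oscillator and a protein
signalling transduction pathway):

* **Tempered Bayesian gradient matching** (`lb2`, `lb10`, `inf`): a GP
  prior on the latent states gives a closed-form conditional
  `xdot_s | x_s ~ N(mu_s, A_s)`; a product of experts links it to the ODE
  gradients with a mismatch variance `gamma`, yielding per species

      p(x_s | theta, eta, gamma) = N(x_s | phi_s, K_eta) · N(f_s | mu_s, A_s + gamma I).

  Parallel MCMC chains target power posteriors `prior · likelihood^alpha`
  with `alpha_i = ((i-1)/(M-1))^5`, each rung paired with a fixed `gamma`
  from a geometric ladder starting at 1 (log-base-2 or log-base-10
  increments; the coldest rung forces slope agreement) or with `gamma`
  sampled (`inf`).  States and hyperparameters are updated through the
  whitening `x = phi + L_eta u`; chains exchange full states via swap moves.

* **RKHS penalised likelihood** (`gon`, `gon_cross`): writing the ODE as
  `xdot_s = g_s - delta_s x_s` and approximating d/dt by a
  difference-quotient matrix `D`, the transformed states solve the ridge
  problem `xtilde = K (K + 2 lambda Sigma)^-1 ytilde` with kernel
  `K = (R'R)^-1`, `R = D + delta I`.  The penalised log-likelihood is
  maximised over `theta` with the penalty `lambda` chosen by AIC or by
  threefold cross-validation (which rejects numerically singular
  `lambda`s and is the robust variant on the pathway model).

A synthetic-data module reproduces the benchmark regimes (grids, noise
models, signal-to-noise settings) exactly, and an evaluation module
provides the comparison metrics (absolute errors, function-space RMS,
error-ECDFs with one-sided KS tests).

## Worked example

```python
from gradmatch import FHN, regime_dataset, run_sampler
from gradmatch.evaluation import point_estimate

dataset = regime_dataset("fhn_cs_20", seed=101)   # 20 noisy points, one period
out = run_sampler(dataset, FHN, mode="lb10", chains=4, iterations=8000,
                  burn_in=4000, thin=10, seed=1, fix_sigma=True,
                  sample_eta=False)
print(point_estimate(out.theta_target))
```

Running `python examples/fhn_tempered_sampling.py` (which is the same
computation with reporting) prints:

```
data: 20 observations of 2 species, noise sd [0.5 0.4]
retained samples : 400
swap acceptance  : 0.02
 parameter    truth   median  abs err
     alpha    0.200    0.187    0.013
      beta    0.200    0.688    0.488
       psi    3.000    2.384    0.616
```

The medians are the sampler's point estimates.  `alpha` is recovered
closely; at this noise level (sd 0.5/0.4 on a signal of amplitude ~2)
and 20 observations per period, `beta` and `psi` carry the attenuation
bias that gradient matching exhibits on sparse, noisy data — the
posterior is informative but its centre is pulled toward slower dynamics.

The other scripts in `examples/` demonstrate the RKHS fit on the pathway
(`ptp_rkhs_fit.py`), the GP derivative conditional that powers the
gradient match (`gp_derivative_matching.py`), and the evaluation metrics
(`method_comparison.py`).  Config-driven regime reproductions run via the
CLI:

```
gradmatch experiment --config examples/regimes/ptp_snr10.yaml --out results/ptp
gradmatch sample --model fhn --mode lb10 --data obs.csv --out results/fhn
gradmatch rkhs --model ptp --select cv --data obs.csv --out results/rkhs
```

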