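# Reduced FitzHugh-Nagumo regime: 20 observations on [0, 10],
# additive noise sd (0.5, 0.4), noise sd held at the generating values.
regime: fhn_cs_20
methods: [lb10, lb2]
profile: desk
chains: 4
seed: 1
sigma_regime: fixed_at_truth
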