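# Pathway regime with multiplicative noise (sd 0.1) and the INF sampler
# (gradient-mismatch variance inferred rather than tempered).
regime: ptp_inf
methods: [inf]
profile: desk
chains: 4
seed: 1
sigma_regime: fixed_at_truth
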