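# Protein signalling transduction pathway, 15-point grid, average SNR 10.
regime: ptp_snr
methods: [lb2, gon_cross]
profile: desk
chains: 4
seed: 1
snr: 10.0
sigma_regime: fixed_at_truth
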