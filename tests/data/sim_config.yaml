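# small demonstration cohort used by the CLI golden-file tests
n_founder_couples: 15
n_generations: 5
offspring_mean: 3.0
variant_founder_freq: 0.08
penetrance_carrier: 0.6
penetrance_noncarrier: 0.15
lethal_prob_carrier: 0.7
lethal_prob_noncarrier: 0.15
seed: 202
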