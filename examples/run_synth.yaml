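# Bundled synthetic scenario: two cohorts, 100 samples per group,
# latent-factor loading 0.95, shared 4-gene persistent core.
mode: synth
hub: MYC
rs_min: 0.3
p_max: 0.05
alpha: 0.05
seed: 1
samples_per_group: 100
coexpr_strength: 0.95
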