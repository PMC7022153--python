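# Reference synthetic configuration for the end-to-end pipeline.
# A compact accelerated-longitudinal cohort: 120 subjects aged 14-26 y,
# 1-3 scans each, 24 cortical + 6 subcortical regions, planted mixed
# maturational-index structure and one annotation map coupled at -0.56.
simulation:
  n_subjects: 120
  n_cortical: 24
  n_subcortical: 6
  seed: 42
n_spins: 300
min_edges: 10
alpha: 0.05
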