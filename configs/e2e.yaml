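# Demonstration pipeline configuration: default synthetic-cohort study
# conditions with a trimmed training budget for a quick end-to-end run.
seed: 11
training:
  n_repeats: 3
  max_epochs: 150
  patience: 30
phenotypes: [mmse, moca, adas11, ravlt_immediate]
top_k: 10
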