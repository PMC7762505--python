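# Demo run: small synthetic cohort at test-scale signal parameters.
seed: 42
synth:
  cohort:
    n_participants: 12
    target_mf_outcome_corr: -0.5
  signal: {}
spectral: {}
stats:
  n_resamples: 2000
  q_level: 0.05
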