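# Two-arm demo cohort for the end-to-end pipeline command.
groups:
  - name: metastatic
    n_subjects: 6
    mean_fraction: 0.45
    sd_fraction: 0.12
  - name: control
    n_subjects: 6
    mean_fraction: 0.08
    sd_fraction: 0.05
scene:
  noise_sigma: 20.0
quantile: 0.0
rule_threshold: 20.0
classify: true
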