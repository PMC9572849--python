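# End-to-end simulated two-group cohort run.
out_dir: out
seed: 1
window_mode: subsegment
thresholds: {stress: 15, anxiety: 8, depression: 10, apathy: 14}
peaks: {prominence_fraction: 0.05, min_separation: 0.1}
simulate:
  n_group1: 2
  n_group2: 3
  # overrides applied on top of the built-in reference group configs
  group1: {}
  group2: {}
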