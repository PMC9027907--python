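# Headline configuration: design 3 with 6 evenly spaced interims (every 37
# subjects up to 220), evaluated under all five response scenarios.
# Run with:  commtrial grid examples/configs/design3_6interims.yaml
design:
  preset: design3
scenarios:
  - preset: harmful
  - preset: "null"
  - preset: small
  - preset: target
  - preset: large
interim_counts: [6]
n_sims: 10000
seed: 20220421
max_n: 256
accrual:
  mean_rate: 2.0
  visit_delay: 12.0
variance_prior:
  weight: 1.0
  scale: 0.07
interim_data: completed
output_dir: commtrial_out/design3_6interims
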