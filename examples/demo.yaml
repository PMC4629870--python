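# Full default demonstration run: unamended slurries, 0-80 degC grid,
# five sampling series up to day 100, 5% measurement noise.
out_dir: out
seed: 1
design:
  scenario: unamended
  time_points: [15, 40, 62, 80, 100]
  replicates: 3
  noise_cv: 0.05
kinetics:
  break_grid: [30, 60, 1]
balance:
  split_temp: 43
partition:
  pairing: max
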