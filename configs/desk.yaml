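# Desk-scale run: 3 subjects, reduced FBCSP grid, completes in minutes.
protocol:
  task: words
  n_subjects: 3
  trials_per_class: 20
signal_model:
  snr: 1.0
  blink_rate: 2.0
preprocess:
  band: [2.0, 40.0]
  target_fs: 128.0
  blink_threshold: 0.8
families: [rlda]
grids:
  rlda:
    nsf: [2, 3]
    miql: [6, 8]
    nof: [8, 10]
k: 4
modes: [intra]
seed: 0
out_dir: results/desk
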