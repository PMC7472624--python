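# Full-scale imagined-vowels study design: 15 subjects, 5 Spanish vowels,
# 40 trials/class at 1024 Hz, 4-fold nested CV over the full grids.
protocol:
  task: vowels
  n_subjects: 15
  trials_per_class: 40
signal_model:
  snr: 1.0
  blink_rate: 2.0
preprocess:
  band: [2.0, 40.0]
  target_fs: 128.0
  blink_threshold: 0.8
families: [svm, rdf, rlda, shallow_cnn, deep_cnn, eegnet]
grids: {}
k: 4
modes: [intra, inter]
seed: 0
out_dir: results/paper_vowels
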