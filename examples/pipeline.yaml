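# A desk-scale run: 4 participants, 4 tagged videos + 1 filler trial.
sim:
  n_participants: 4
  n_videos: 4
  n_trials: 5
  seed: 0
  annot_agreement: 0.92
  annot_unclear: 0.04
  band_gains:
    1: {alpha: 1.5}
    2: {}
  gain_vdeps: [colour, balance, movement, light]
model:
  conv_filters: [8, 16]
  dense_units: 32
  learning_rate: 0.002
  max_epochs: 4
  patience: 2
k: 3
vdeps: [colour, movement]
seed: 42
out_dir: scratch/demo_run
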