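# Demo simulation config: all four synthetic fixture families.
# Run:  pclong simulate --config examples/demo_config.yaml --seed 1 --out demo_out
spatial:
  box_extent: [500.0, 500.0, 500.0]
  n_cells_per_subset: [400, 120]
  process: clustered
  n_parents: 10
  offspring_sd: 10.0
  llpc_cluster_affinity: 0.9

tracks:
  n_tracks: {sessile: 60, motile: 60}
  frame_interval: 3.0
  n_frames: 20
  step_sd: {sessile: 0.2, motile: 2.0}
  arrest_prob: {sessile: 0.5, motile: 0.0}
  channel_means: {sessile: [80.0, 100.0], motile: [120.0, 100.0]}
  channel_sd: 1.0

decay:
  n0: 1000.0
  t_half: 58.0
  timepoints: [5.0, 30.0, 90.0, 150.0]
  noise_cv: 0.2
  n_replicates: 5

repertoire:
  n_mice: 3
  n_clones_per_sample: 120
  reads_per_sample: 2400
  n_public_clones: 15
  public_llpc_bias: 0.75
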