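# Demo pipeline: synthetic scene -> profiles/targeting/comets/tracks -> stats.
# Run with:  mtcortex run-all --config examples/demo_config.yaml --out scratch/demo
seed: 1
stages: [profiles, targeting, comets, tracks, stats]
scene:
  field: [30.0, 30.0]
  pixel_size: 0.1
  n_cells: 8
profiles:
  n_positions: 10
  enrichment_control: 1.0
  enrichment_treated: 0.5
  junction_density: 6.0
  noise_sd: 1.0
targeting:
  n_filaments: 200
  target_angle: 70.0
  kappa: 4.0
comets:
  density: 5.0
  min_separation: 1.5
tracks:
  n_tracks: 100
  v_growth: 12.0
  v_growth_treated: 6.0
  frame_interval: 2.0
  n_frames: 40
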