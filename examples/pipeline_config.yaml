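# Full-pipeline configuration for `serialdep run --config ... --seed ... --outdir ...`
# Omitted keys fall back to the defaults documented in serialdep.PipelineConfig.
n_participants: 15
rt_base_sd: 50.0
design:
  n_sessions: 2
  trials_per_session: 1000
  p_distractor: 0.5
  probe_delta_range: 65.0
  n_locations: 4
  block_order: alternate
observer:
  attract_amp_prev_probe: 1.4
  attract_width_prev_probe: 25.0
  repulse_amp_prev_probe: 0.5
  repulse_width_prev_probe: 60.0
  repulse_amp_distractor: 0.5
  repulse_width_distractor: 30.0
  motor_noise_sd: 8.0
  lapse_rate: 0.02
width_grid: [10, 80, 1]
similarity_threshold: 45.0
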