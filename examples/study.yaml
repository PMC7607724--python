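# Full study configuration: every value shown here is the default, so an
# empty file (or no --config at all) runs the same analysis.
pipeline:
  blink_pre_s: 0.05        # NaN window before each device blink (s)
  blink_post_s: 0.20       # NaN window after each device blink (s)
  mad_k: 3.0               # outlier threshold in raw MADs
  nan_frac_max: 0.40       # strict trial-exclusion fraction
  lp_cutoff_hz: 10.0       # FIR low-pass cutoff
  fir_length: 201          # FIR taps (odd, linear phase)
  kaiser_beta: 5.0         # Kaiser window beta (~50 dB sidelobes)
  baseline_window: [-0.5, 0.0]   # [start, end) relative to onset (s)
  metric_window: [0.5, 1.0]      # onset-relative start, offset-relative end
  exclusion_window: [-0.5, 1.0]  # onset-relative start, offset-relative end
  ms_threshold_k: 15.0     # velocity threshold in median-based SDs
  ms_min_duration_s: 0.006 # event persistence requirement
  ms_kernel_sd_s: 0.02     # rate-curve Gaussian kernel SD
  ms_criterion: elliptic   # elliptic | speed
  none_response_policy: incorrect  # incorrect | exclude

simulate:
  n_participants: 10
  n_trials_per_condition: 28   # over 4 blocks (7 per cell per block)
  sampling_rate: 500.0
  duration_range_s: [1.4, 4.8]
  tonic_pupil: 1000.0          # a.u.
  response_amplitude_base: 20.0
  beta_clarity: 10.0           # added evoked peak for low-SNR trials
  beta_ambiguity: 6.0          # added evoked peak for high-ambiguity trials
  beta_interaction: -4.0       # sub-additive combination
  noise_sd: 20.0
  drift_sd: 30.0
  subject_amplitude_sd: 8.0
  subject_effect_sd: 12.0
  blink_rate_hz: 0.1
  spike_rate_hz: 0.2
  ms_base_rate_hz: 1.5
  ms_inhibition_depth: 0.7
  ms_inhibition_t_s: 0.3
  accuracy:
    high_snr/LA: 0.92
    high_snr/HA: 0.92
    low_snr/LA: 0.88
    low_snr/HA: 0.82
  seed: 0

run:
  simulate: true
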