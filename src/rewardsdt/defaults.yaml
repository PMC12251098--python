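# Study-level defaults: analysis windows, electrode sets, statistical settings.
# Electrode sets and windows are data, not code: override in a user config.
seed: 0
n_participants: 24
sessions: [space_specific, choice_specific]

schedule:
  n_blocks: 12
  trials_per_block: 48

observer:
  d_mean: 0.7
  c_mean: 0.12
  space:
    delta_d_vr: 0.5
    delta_d_fx: -0.5
    delta_rt_vr: -20.0
    delta_rt_fx: 34.0
  choice:
    delta_c_vr: -0.5
    rt_choice_bias_ms: -24.0
  between_observer_sd: 0.15   # jitter of planted modulations across observers
  lapse_rate: 0.0

gaze:
  enabled: true
  trials_per_session: 96      # traces generated for the first trials of the session
  fs_hz: 1000
  msc_window_ms: [150, 350]
  rate_window_ms: 100
  rate_step_ms: 25
  direction_cone_deg: 45
  rate_attended: 0.12
  rate_unattended: 0.06

eeg:
  enabled: true
  trials_per_session: 96
  fs_hz: 250
  iaf_hz: 10.0
  band_hz: [0.5, 35]
  erp_trim_ms: [-200, 700]
  baseline_ms: [-200, 0]
  alpha_post_window_ms: [450, 950]
  alpha_pre_window_ms: [-500, 0]
  norm_band_hz: [15, 35]
  iaf_search_band_hz: [7.5, 13]
  delta_n2pc_uv: 0.75
  delta_p300_uv: 0.75
  alpha_suppression: 0.25
  pre_alpha_suppression: 0.15
  components:
    N2pc: {channels: [PO3, PO4, PO7, PO8, O1, O2], window: [150, 210], polarity: -1}
    P2a: {channels: [F1, F2, F3, F4, C1, C2, C3, C4, FC1, FC2], window: [150, 210], polarity: 1}
    P300: {channels: [PO3, PO4, PO7, PO8, O1, O2], window: [230, 480], polarity: 1}

dynamics:
  width: 9
  shift: 2
  offsets: [-2, 14]
  n_perm: 1000

markers:
  n_perm_beta: 2000           # scaled down from the headline 100,000 for routine runs
  pb_beta: 0.2

stats:
  alpha_cluster: 0.05
  n_perm_cluster: 1000
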