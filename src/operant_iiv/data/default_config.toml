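# Default simulation configuration: a 16-rat "SHR-like" (high-dispersion,
# bursty, ADHD-model-like) group versus a 15-rat "WKY-like" control group,
# five daily 90-min sessions of five 18-min segments, VI-180 s reinforcement.
# All values are preset modelling choices for the synthetic generator, not
# estimates from any real dataset.

[design]
n_sessions = 5
session_duration_s = 5400.0
n_segments = 5
vi_mean_s = 180.0

[strain.SHR]
n_rats = 16
base_lever_rate = 4.0
rat_rate_sd_log = 0.25
segment_dispersion_sd_log = 0.5
dispersion_trend_per_segment = 0.05
burst_prob = 0.35
burst_irt_mean_s = 0.25
nonburst_irt_mean_s = 3.0
incorrect_door_rate = 1.5
incorrect_lever_frac = 0.25

[strain.WKY]
n_rats = 15
base_lever_rate = 2.5
rat_rate_sd_log = 0.25
segment_dispersion_sd_log = 0.2
dispersion_trend_per_segment = -0.03
burst_prob = 0.15
burst_irt_mean_s = 0.3
nonburst_irt_mean_s = 3.0
incorrect_door_rate = 0.5
incorrect_lever_frac = 0.15
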