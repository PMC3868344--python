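alpha_intakes: 20
availability_start_day: 5
beta_ts_per_hour: 0.015
compulsion_const: 1.0
cs_scale: 0.3
d_abstinence_onset_h: 2
d_floor_frac: 0.35
d_relax_per_hour: 0.02
d_rise_per_intake: 0.02
delta_t0: 0.0045
dose_unit: 1.0
gamma_m: 5.0
gamma_ts_per_hour: 0.001
heal_relax_per_hour: 0.005
horizon_days: 160
inhibition_const: 1.0
lambda_ts: 8.0
learning_pair_window_h: 3
learning_stage_cap: 4
n_runs: 100
omega_a: 0.5
omega_d_init: 0.45
omega_h: 3.0
omega_max: 1.0
omega_min: 0.0
omega_p_init: 0.75
omega_q: 0.55
omega_s_init: 0.6
p_heal_per_hour: 0.3
p_learn_per_hour: 0.0065
p_persist: 0.13
p_relax_per_hour: 0.0
p_rise_per_intake: 0.005
pk_elimination_per_min: 0.005776
pk_volume: 1.0
q_relax_per_hour: 0.0
q_rise_per_intake: 0.00065
rc_amplitude: 1.0
rc_period_min: 30.0
rc_tail_rate_per_min: 0.05
rd_baseline: -0.08
refractory_min: 30
s_relax_per_hour: 0.02
s_rise_per_hour: 0.028
t0_init: 5.0
t50: 5.0
trigger_ad_magnitude: 0.3
trigger_ap_magnitude: 0.3
trigger_aq_magnitude: 0.3
trigger_as_magnitude: 0.3
ts_init: 4.5
weight_step: 0.05
withdrawal_end_h: 720
withdrawal_onset_h: 12
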