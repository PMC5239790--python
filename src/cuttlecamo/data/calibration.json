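{
 "control_change_pct": 1.69,
 "change_vs_width_slope": 0.12,
 "change_vs_width_intercept_pct": 1.72,
 "variance_sigmoid_params": [
  0.3364,
  3.0979,
  8.0472,
  11.5526
 ],
 "mantle_mean_cm": 10.2,
 "mantle_sd_cm": 1.2,
 "mantle_min_cm": 7.2,
 "mantle_max_cm": 12.3,
 "responder_change_sd_pct": 1.732,
 "baseline_step_halfrange_pct": 0.042403,
 "nominal_gain": 0.0017147,
 "speed_mean_cm_s": 8.0,
 "speed_jitter_frac": 0.25,
 "animal_jitter_sigma": 0.15,
 "schema_version": 1
}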