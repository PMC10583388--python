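# Calibrated simulator preset (versioned; regenerate with `nevolt calibrate-noise`).
#
# The electrode block parameterizes the synthetic carbon-fiber response;
# `gain_nA_per_ug_ml` is set so a 0.5 µg/mL bolus yields a pipeline peak i°
# near 300 nA, and `noise_sd_nA` so the dose-ladder detection threshold
# falls between 0.01 and 0.1 µg/mL.  `subjects.gain_sigma` is the log-normal
# spread of per-animal electrode gain (placement variability), calibrated
# against the pooled dose-linearity correlation.  The cohort block draws Q°
# log-uniformly over the observed SpNS range and is calibrated so the
# Q°->TNF power fit explains ~40% of TNF variance.
bolus_kinetics:
  k_clear_per_s: 0.02
  k_rise_per_s: 0.35
calibration_version: 3
cohort:
  a: 5.0
  b: 1.5
  n_sham: 10
  n_stim: 17
  qo_min_uC: 2.3
  qo_max_uC: 121.7
  sham_tnf_mean_pg_ml: 7500.0
  sham_tnf_sd_pg_ml: 2500.0
  tnf_sigma: 1.65
electrode:
  asym_ratio: 0.6
  c_dl_nF: 1.5
  drift_rate_nA_per_min: 0.5
  drift_rw_sd_nA: 0.05
  e_ox_V:
    blood: 0.72
    pbs: 0.57
    spleen: 0.88
  e_red_V: 0.0
  gain_nA_per_ug_ml: 642.18
  noise_sd_nA: 6.189
  peak_width_V: 0.12
  red_fraction: 0.3
stim_kinetics:
  k_diff_per_s: 0.005
  km_ug_ml: 0.1
  release_gain_ug_ml_s: 0.025
  u50_uC_per_s: 0.5
  vmax_ug_ml_s: 0.0015
subjects:
  gain_sigma: 0.806
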