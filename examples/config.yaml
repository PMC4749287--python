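# Example pipeline configuration: a small two-trait synthetic cohort.
# Run:  twindelta report --config examples/config.yaml --out results/
simulate:
  n_mz_pairs: 226
  n_dz_pairs: 276
  age_range: [18, 67]
  prop_female: 0.54
  follow_up_years: 12
  seed: 1
  traits:
    - name: TC            # total cholesterol, log-normal
      mu_baseline: 1.68   # log mmol/l
      var_level: [0.5, 0.1, 0.0, 0.4]     # (a2, c2, d2, e2) of the baseline level
      var_change: [0.48, 0.0, 0.0, 0.52]  # (a2, c2, d2, e2) of the change
      total_sd_level: 0.18
      total_sd_change: 0.12
      beta_time: 0.02
      beta_age: 0.002
      beta_sex: -0.02
      lognormal: true
    - name: HIP           # hip circumference, shared-environment change
      mu_baseline: 4.57   # log cm
      var_level: [0.5, 0.1, 0.0, 0.4]
      var_change: [0.0, 0.43, 0.0, 0.57]
      total_sd_level: 0.07
      total_sd_change: 0.04
      beta_time: 0.06
      beta_age: 0.002
      beta_sex: -0.02
      lognormal: true

traits: [TC, HIP]
log_traits: all
sd_cut: 3.0
alpha: 0.05
bootstrap_reps: 200
seed: 1
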