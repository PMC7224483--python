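# Default run configuration. Weight means for lam and alpha_home are the
# output of the packaged two-anchor calibration (see the methods note);
# rerun `surgesim calibrate` to regenerate them for a different seed or
# facility table.
population:
  n_agents: 100000
  gender_split: 0.5
  education_probs: [0.53422, 0.16642, 0.29936]
  wealth_probs: [0.20131, 0.19959, 0.19937, 0.20052, 0.19921]
  age_probs: [0.33261, 0.08264, 0.17547, 0.40928]
  income:
    median: 554986
    q25: 341936
    q75: 842990
  density:
    side: 60.0
    cluster_center: [10.0, 12.0]
    cluster_sigma: 6.0
    cluster_weight: 0.65
  seed: 0
facilities:
  table: null   # packaged nine-hospital survey table
  coords: null  # packaged fixed coordinates
weights:
  gamma: [1.5, 0.3]
  delta: [0.06, 0.015]
  lam: [2.7516, 0.5503]       # calibrated to the two anchor no-show rates
  alpha_home: [-0.4048, 0.3]  # calibrated to the two anchor no-show rates
engine:
  dose: 0
  batch_size: 20000
  n_runs: 50
  master_seed: 0
  money_form: capped_share
experiment:
  anchors: [[0, 0.566], [280000, 0.300]]
  dose_grid: {start: 0, stop: 1000000, step: 10000}
  sweep_n_runs: 10
  sweep_batch_size: 5000
  sweep_statistic: expected
  plateau_epsilon: 1.0e-9
  subgroup_dose: 280000
  calibration_tolerance: 0.015
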