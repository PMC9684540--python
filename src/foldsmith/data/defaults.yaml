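# Single source of truth for the numeric defaults the CLI exposes.
# A --config YAML with the same keys overrides any subset.
filters:
  max_helix_bend_deg: 15.0
  constraint_tolerance_sd: 2.0
  pair_distance_min: 4.2
  pair_distance_max: 5.7
  omega_tolerance_deg: 20.0
  rama_margin_deg: 5.0
  clash_cutoff: 2.5
constraints:
  default_target: 8.0
  default_sd: 2.0
  default_function: harmonic
  default_bound_width: 1.0
build:
  moves_per_trajectory: 2000
  trajectories_per_task: 20
  perturbations_per_task: 100
  temp_high: 2.0
  temp_low: 0.5
  restarts: 3
  backtracks: 6
  max_total_trajectories: 100000
layers:
  core_min_burial: 5
  surface_max_burial: 2
  burial_radius: 10.5
stability:
  success_threshold: 0.5
forest:
  n_trees: 500
  criterion: gini
  bootstrap: true
  max_features: sqrt
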