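# Bundled Hes1 oscillator study: every field mirrors the package defaults,
# shown here explicitly so they are easy to edit.
model: hes1
model_overrides: {}        # e.g. {x0: [0.0, 0.0, 0.0]}
dataset_path: null         # CSV with output_id,time_min,mean,sd,schedule_id
seed: 1
outdir: null

design:
  admissible_times: [0, 2, 5, 8, 10, 50, 100, 150, 200]   # minutes
  input_bounds: [[0.01, 2.0]]       # alpha scales the transport rate k1
  input_resolution: [0.05]          # 40 discrete levels
  base_input: [1.0]
  target_input: [1.0]
  measurement_species: null         # null = all model outputs (m, P1+P2)
  sampling_dt: 10.0                 # minutes, measurement grid over t_span
  K: 8                              # unique measurements to design
  target_states: [m, P1, P2]
  optimize_input: true              # false = measurement-only design
  input_grid_max_depth: 5           # up to 33-node 1-D grids over the input level
  tree_top_candidates: 5
  hampel_window: 3
  hampel_n_sigma: 3.0

screening:
  n_lhs: 10000
  N_A: 2000
  T_A: 2.0
  C: 12                             # representatives per dynamics cluster
  screen_max_depth: 3
  focused_max_depth: 5
  rel_tol: 0.10
  abs_tol: 5.0
  focused_rounds: 5
  cluster_sample: 600
  k_max: 6

plant:
  noise_frac: 0.10
  n_replicates: 3
  initial_points: [[m, 10.0], [m, 20.0], [m, 60.0],
                   [P1+P2, 10.0], [P1+P2, 20.0], [P1+P2, 60.0]]
  nominal_unknowns: null            # null = registry nominal (2.4, 2, 0.025)

noise_zeta: [0.05, 0.10, 0.01]      # zeta_b, zeta_s, zeta_t
dense_grid_points: 151
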