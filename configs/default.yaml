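# Default run configuration (all values shown; CLI flags override).
grid_rows: 30
grid_cols: 30
complexities: [0, 1, 2, 3]
timesteps: 100          # foraging saccades per episode (25 level-2 cycles)
trials: 100             # categorisation trials per series
n_seeds: 20             # training seeds per complexity in sweeps
n_series_seeds: 20      # cut-out series seeds in sweeps
master_seed: 1
risk_weight: 1.0
ambiguity_weight: 1.0
novelty_weight: 24.0    # Dirichlet information-gain weight in G
dirichlet_seed: 1.0     # prior count mass per B2 column
dirichlet_rate: 1.0     # count mass added per level-2 cycle
pref_pigment: 4.0       # log-preference for observing a pigment
pref_background: -4.0
epsilon: 0.001          # likelihood floor
max_saccade: null       # saccade length limit (null = whole grid reachable)
plus_penalty: -8.0      # decision-stage log-penalty on the "+" shape
decision_rule: sample   # "sample" (posterior sampling) or "argmax"
band_row: null          # null = n_rows // 2 - 1
out_dir: outputs
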