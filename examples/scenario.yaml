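# Progression scenario for `rootstage simulate`.
# A wild-type baseline, a 1.5x-faster loss-of-function mutant, and a
# 0.67x-slower overexpressor; all fields optional (defaults shown).
stage_rates: [0.13, 0.13, 0.13, 0.13, 0.13, 0.13, 0.13]  # per-hour exit rates I->II .. VII->E
genotype_multipliers:
  Col0: 1.0
  myb93: 1.5
  MYB93oe: 0.67
initiation_intensity: 3.0      # expected LRP initiations per cm of PR
pr_length_mean_cm: 6.0
pr_length_sd_cm: 1.0
initiation_lag_h_mean: 2.0     # stimulus-to-first-division delay (induced assay)
observation_times_h: [18.0, 42.0]
root_age_h: 96.0               # LRP age horizon for the whole-root survey
n_roots: 30
erlang_k: 1                    # 1 = exponential dwell times; >1 = Erlang-k
seed: 0
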