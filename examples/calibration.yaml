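# Calibration scenario for `rootstage calibrate`.
# Null regime by default; add alt_probs for a power estimate.
scenario_id: uniform4-null
null_probs: [0.25, 0.25, 0.25, 0.25, 0.0, 0.0, 0.0, 0.0]
n_a: 40
n_b: 40
reps: 500
B: 1000
alpha: 0.05
seed: 1
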