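# Default comparative sweep: the five studied designs across the ten
# reference scenarios, at the slight positive correlation preset
# R = R_max / 3, 10,000 replicates of 90-patient trials.
designs:
  - top_pp
  - simon_pp
  - bop_pp
  - top_joint
  - itop_joint
scenarios: reference
r_preset: pos1
reps: 10000
seed: 2024
out_dir: toptrial-results
mean_interarrival: 6.0
accrual_mode: exponential
t_eff: 180.0
t_tox: 42.0
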