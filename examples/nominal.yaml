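# Nominal severe-patient experiment. Every omitted key keeps its default,
# so an empty file is equivalent; shown here are the most commonly varied
# settings with their nominal values.
model:
  kappa_P: 0.85      # skin permeability (day^-1) — FLG-risk axis
  alpha_I: 0.05      # innate eradication rate (day^-1) — immune-risk axis
  K_on: 2.0          # kallikrein on-level (switch shares P thresholds)
weights:
  k1: 0.5
  k2: 1.0
  k3: 10.0
  k4: 10.0
  P_target_induction: 24.0
  P_target_maintenance: 26.0
bounds:
  C_max_induction: 50.0
  C_max_maintenance: 50.0
  T_r_max_weeks: 8    # converted to days on load
  T_m: 7.0
  E_bar: 0.04
de:
  population_size: 30
  generations: 1000
scenario: nominal
n_cycles: 8
seed: 1
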