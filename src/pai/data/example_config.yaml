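# Variable-role config for the bundled single-patient example.
# Centering constants are fixed at the values under which the reference
# coefficient set was estimated (not recomputed from data).
arms: [CBT, ADM]
outcome:
  column: end_hrsd
  transform: sqrt
better_direction: lower
variables:
  intake_hrsd: {role: prognostic, kind: continuous, center: 23.75}
  age: {role: prognostic, kind: continuous, center: 40.33}
  iq_band: {role: prognostic, kind: ordinal3}
  chronic: {role: prognostic, kind: binary, positive_label: chronic, negative_label: nonchronic}
  married: {role: prescriptive, kind: binary, positive_label: married, negative_label: unmarried}
  employed: {role: prescriptive, kind: binary, positive_label: employed, negative_label: unemployed}
  life_stressors: {role: prescriptive, kind: continuous, center: 3.65}
  personality_disorder: {role: prescriptive, kind: binary, positive_label: pd, negative_label: no_pd}
  prior_adm_trials: {role: prescriptive, kind: capped_count, cap: 2, center: 0.72}
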