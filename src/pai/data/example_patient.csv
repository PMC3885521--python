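patient_id,arm,intake_hrsd,age,iq_band,chronic,married,employed,life_stressors,personality_disorder,prior_adm_trials,end_hrsd
EX001,CBT,20,56,high,chronic,unmarried,unemployed,3,no_pd,2,
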