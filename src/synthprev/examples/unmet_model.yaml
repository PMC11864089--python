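# Example model specification for the unmet-need outcome.
outcome: unmet_need
predictors: [sex, age_group, srmh, mood_anx, life_stress, life_sat]
group: area_id
use_weights: false
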