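# Example model specification for the perceived-need outcome: the common
# regional predictor set (sex, age, self-reported mental health, diagnosed
# mood/anxiety disorder, life stress, life satisfaction), with the random
# intercept on health regions.
outcome: perceived_need
predictors: [sex, age_group, srmh, mood_anx, life_stress, life_sat]
group: area_id
use_weights: false
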