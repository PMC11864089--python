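# End-to-end desk-scale study: develop region-specific models on the 2018
# emulated survey, validate synthetic estimates on the 2019/2020 emulations.
seed: 20180101
criterion: bic
select: true
group: area_id
use_weights: false
bootstrap: false
dev_label: dev2018
datasets:
  dev2018: {example: dev2018}
  val2019: {example: val2019}
  val2020: {example: val2020}
regions:
  Atlantic: ["10", "11", "12", "13"]
  Central: ["24", "35"]
  Western: ["46", "47", "48", "59"]
outcomes:
  perceived_need:
    predictors: [sex, age_group, srmh, mood_anx, life_stress, life_sat]
  unmet_need:
    predictors: [sex, age_group, srmh, mood_anx, life_stress, life_sat]
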