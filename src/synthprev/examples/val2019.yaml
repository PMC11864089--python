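predictors:
- name: sex
  levels:
  - female
  - male
  probs:
  - 0.506
  - 0.494
- name: age_group
  levels:
  - 12-34
  - 35-49
  - 50-64
  - 65+
  probs:
  - 0.3
  - 0.25
  - 0.25
  - 0.2
- name: srmh
  levels:
  - good
  - fair
  - poor
  probs:
  - 0.82
  - 0.13
  - 0.05
- name: mood_anx
  levels:
  - 'no'
  - 'yes'
  probs:
  - 0.87
  - 0.13
- name: life_stress
  levels:
  - low
  - high
  probs:
  - 0.71
  - 0.29
- name: life_sat
  levels:
  - satisfied
  - dissatisfied
  probs:
  - 0.93
  - 0.07
regions:
- area_id: '1011'
  province_id: '10'
  n: 600
  overrides: &id001
    srmh:
    - 0.8
    - 0.14
    - 0.06
    life_stress:
    - 0.74
    - 0.26
- area_id: '1012'
  province_id: '10'
  n: 600
  overrides: *id001
- area_id: '1101'
  province_id: '11'
  n: 500
  overrides: &id002
    mood_anx:
    - 0.88
    - 0.12
- area_id: '1102'
  province_id: '11'
  n: 500
  overrides: *id002
- area_id: '1201'
  province_id: '12'
  n: 500
  overrides: &id003
    srmh:
    - 0.79
    - 0.15
    - 0.06
    mood_anx:
    - 0.85
    - 0.15
- area_id: '1202'
  province_id: '12'
  n: 500
  overrides: *id003
- area_id: '1203'
  province_id: '12'
  n: 500
  overrides: *id003
- area_id: '1301'
  province_id: '13'
  n: 700
  overrides: &id004
    life_stress:
    - 0.7
    - 0.3
- area_id: '1304'
  province_id: '13'
  n: 700
  overrides: *id004
- area_id: '2401'
  province_id: '24'
  n: 1200
  overrides: &id005
    life_stress:
    - 0.68
    - 0.32
    life_sat:
    - 0.94
    - 0.06
- area_id: '2403'
  province_id: '24'
  n: 1200
  overrides: *id005
- area_id: '2404'
  province_id: '24'
  n: 1200
  overrides: *id005
- area_id: '2406'
  province_id: '24'
  n: 1200
  overrides: *id005
- area_id: '2412'
  province_id: '24'
  n: 1200
  overrides: *id005
- area_id: '3536'
  province_id: '35'
  n: 1600
- area_id: '3544'
  province_id: '35'
  n: 1600
- area_id: '3553'
  province_id: '35'
  n: 1600
- area_id: '3570'
  province_id: '35'
  n: 1600
- area_id: '3595'
  province_id: '35'
  n: 1600
- area_id: '4610'
  province_id: '46'
  n: 750
  overrides: &id006
    mood_anx:
    - 0.86
    - 0.14
- area_id: '4640'
  province_id: '46'
  n: 750
  overrides: *id006
- area_id: '4704'
  province_id: '47'
  n: 750
  overrides: &id007
    srmh:
    - 0.83
    - 0.12
    - 0.05
    life_stress:
    - 0.75
    - 0.25
    mood_anx:
    - 0.89
    - 0.11
- area_id: '4706'
  province_id: '47'
  n: 750
  overrides: *id007
- area_id: '4831'
  province_id: '48'
  n: 1000
  overrides: &id008
    age_group:
    - 0.32
    - 0.27
    - 0.24
    - 0.17
    life_stress:
    - 0.7
    - 0.3
- area_id: '4832'
  province_id: '48'
  n: 1000
  overrides: *id008
- area_id: '4833'
  province_id: '48'
  n: 1000
  overrides: *id008
- area_id: '5913'
  province_id: '59'
  n: 1200
  overrides: &id009
    srmh:
    - 0.81
    - 0.13
    - 0.06
    life_sat:
    - 0.92
    - 0.08
- area_id: '5921'
  province_id: '59'
  n: 1200
  overrides: *id009
- area_id: '5922'
  province_id: '59'
  n: 1100
  overrides: *id009
outcomes:
- name: perceived_need
  random_intercept_sd: 0.3
  coefficients:
    Intercept: -2.2059
    sex[male]: -0.35
    age_group[35-49]: -0.3
    age_group[50-64]: -0.65
    age_group[65+]: -1.1
    srmh[fair]: 1.6
    srmh[poor]: 2.6
    mood_anx[yes]: 1.9
    life_stress[high]: 0.9
    life_sat[dissatisfied]: 0.8
- name: unmet_need
  random_intercept_sd: 0.3
  coefficients:
    Intercept: -3.974
    sex[male]: -0.25
    age_group[35-49]: -0.25
    age_group[50-64]: -0.55
    age_group[65+]: -1.2
    srmh[fair]: 1.4
    srmh[poor]: 2.3
    mood_anx[yes]: 1.2
    life_stress[high]: 0.8
    life_sat[dissatisfied]: 0.9
weight_sigma: 0.5
cluster_size: 10
n_bootstrap: 0
seed: 2019
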