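# Cohort design matched to the study demographics: abacavir arm
drug: abacavir
n_mdr: 25
n_control: 25
weight_kg:
  mdr: {median: 13.2, q1: 9.0, q3: 21.1}
  control: {median: 16.3, q1: 11.5, q3: 23.3}
age_years:
  mdr: {median: 2.9, q1: 1.4, q3: 9.4}
  control: {median: 5.8, q1: 2.7, q3: 9.6}
suspension_fraction: {mdr: 0.84, control: 0.44}
nasogastric_fraction: {mdr: 0.44, control: 0.24}
lpv_fraction: {mdr: 0.60, control: 0.56}
dose_mg_per_kg: 8.0
interval_h: 12.0
qd_dose_mg_per_kg: 16.0
n_qd_control: 2
n_prior_doses: 10
blq_censoring: true
missed_dose_fraction: 0.074
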