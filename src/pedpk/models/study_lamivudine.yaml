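# Cohort design matched to the study demographics: lamivudine arm
drug: lamivudine
n_mdr: 27
n_control: 27
weight_kg:
  mdr: {median: 13.4, q1: 9.1, q3: 21.4}
  control: {median: 15.6, q1: 11.2, q3: 23.1}
age_years:
  mdr: {median: 4.2, q1: 1.6, q3: 9.6}
  control: {median: 5.7, q1: 1.6, q3: 9.5}
suspension_fraction: {mdr: 0.67, control: 0.37}
nasogastric_fraction: {mdr: 0.44, control: 0.30}
lpv_fraction: {mdr: 0.59, control: 0.59}
dose_mg_per_kg: 4.0
interval_h: 12.0
qd_dose_mg_per_kg: 8.0
n_qd_control: 2
n_prior_doses: 10
blq_censoring: true
missed_dose_fraction: 0.074
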