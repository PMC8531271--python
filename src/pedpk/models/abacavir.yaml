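drug: abacavir
structural:
  cl: 16.3        # L/h, typical oral clearance, 15 kg reference child
  vc: 21.7        # L
  q: 1.42         # L/h
  vp: 12.0        # L
  ka: 1.77        # 1/h
  mtt_tablet: 0.458   # h
  beta_susp: -0.816   # proportional effect of suspension on MTT
  nn: 3.70        # number of transit compartments (continuous)
  f: 1.0          # relative bioavailability (fixed)
  gamma: 3.94     # maturation Hill coefficient
  pmage50: 11.9   # months from conception at 50% maturation
  ref_weight: 15.0
random_effects:
  omega_cl: 0.177   # BSV on CL, log-scale SD
  pi_ka: 0.749      # BOV on ka
  pi_mtt: 1.19      # BOV on MTT
  pi_f: 0.489       # BOV on F
error:
  sigma_prop: 0.192   # proportional residual SD
  sigma_add: 0.0048   # mg/L (fixed to 20% of LLOQ)
  lloq: 0.024         # mg/L
dosing:
  mg_per_kg: 8.0
  interval: 12.0
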