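drug: lamivudine
structural:
  cl: 10.8        # L/h, typical oral clearance, 15 kg reference child
  vc: 26.5        # L
  q: 2.25         # L/h
  vp: 69.8        # L
  ka: 1.07        # 1/h
  mtt_tablet: 0.643   # h
  beta_susp: -0.463   # proportional effect of suspension on MTT
  nn: 6.38        # number of transit compartments (continuous)
  f: 1.0          # relative bioavailability (fixed)
  gamma: 3.32     # maturation Hill coefficient
  pmage50: 10.6   # months from conception at 50% maturation
  ref_weight: 15.0
random_effects:
  omega_cl: 0.147   # BSV on CL, log-scale SD
  pi_ka: 0.660      # BOV on ka
  pi_mtt: 0.774     # BOV on MTT
  pi_f: 0.294       # BOV on F
error:
  sigma_prop: 0.108   # proportional residual SD
  sigma_add: 0.0048   # mg/L (fixed to 20% of LLOQ)
  lloq: 0.024         # mg/L
dosing:
  mg_per_kg: 4.0
  interval: 12.0
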