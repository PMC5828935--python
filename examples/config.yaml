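# Example configuration covering all uadyn commands.

population:
  gfr_range_ml_min: [80, 120]
  fe0_median: 0.07
  fe0_gsd: 1.4
  sua_mean_mg_dl: 5.5
  sua_sd_mg_dl: 0.8

design: default_phase1

simulation:
  physiology: {gfr_ml_min: 100, fe0: 0.07, sua_mg_dl: 6}
  regimens:
    - {drug: lesinurad, dose_mg: 400, times: [0]}
  horizon: 24
  serum_times: [0, 1, 2, 4, 8, 12, 24]
  urine_intervals: [[0, 6], [6, 12], [12, 18], [18, 24]]

fit:
  n_starts: 5
  free:
    cl_i: {init: 0.5, lower: 0.01, upper: 5.0}
    v_ua: {init: 12.0, lower: 2.0, upper: 100.0}
    lesinurad.p50: {init: 8000.0, lower: 100.0, upper: 1.0e+6}
    oxypurinol.p50: {init: 8000.0, lower: 100.0, upper: 1.0e+6}
    febuxostat.p50: {init: 200.0, lower: 1.0, upper: 1.0e+5}
    serum.a: {init: 2.0, lower: 0.01, upper: 50.0}
    serum.b: {init: 0.2, lower: 0.001, upper: 2.0}
    urine.a: {init: 30.0, lower: 0.1, upper: 1000.0}
    urine.b: {init: 0.2, lower: 0.001, upper: 2.0}
  fixed:
    oxypurinol.max_effect: 0.84
    lesinurad.max_effect: 0.56
    febuxostat.max_effect: 1.0

qualify:
  phase3: {n: 200, visit_count: 6, allopurinol_fraction: 0.5}

# The worked patient scenario: serum urate 12 mg/dL, GFR 60 mL/min,
# baseline fractional excretion 0.03.
nomogram:
  sua_base_mg_dl: 12
  gfr_ml_min: 60
  fe0: 0.03
  cl_i: 0.27
  cl_i_range: [0.19, 0.36]
  targets: [0.5]
  increments: [0.0, 0.05, 0.1]
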