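# Base-case inputs: societal cost-effectiveness of 21-gene-assay-guided
# adjuvant chemotherapy in ER+, LN- early breast cancer (2013 JPY).
# Chemotherapy recommendation rates are stored as counts from the 104-patient
# decision-impact cohort so that derived proportions are exact rationals.
# The bundled life table is a synthetic Gompertz-Makeham approximation of
# Japanese female period mortality (see docs/methods.md).
risk_source: japan
life_table: life_table_japan_female_synthetic.csv
groups:
  low:
    n_patients: 50
    n_chemo_pre: 16
    n_chemo_post: 0
    baseline_risk_10y:
      japan: {base: 0.033, low: 0.011, high: 0.100}
      us_uk: {base: 0.054, low: 0.036, high: 0.085}
    rrr_chemo: {base: 0.0, low: 0.0, high: 0.54}
  intermediate:
    n_patients: 37
    n_chemo_pre: 18
    n_chemo_post: 11
    baseline_risk_10y:
      japan: {base: 0.0, low: 0.0, high: 0.0}
      us_uk: {base: 0.137, low: 0.086, high: 0.200}
    rrr_chemo: {base: 0.39, low: 0.0, high: 0.76}
  high:
    n_patients: 17
    n_chemo_pre: 14
    n_chemo_post: 17
    baseline_risk_10y:
      japan: {base: 0.248, low: 0.157, high: 0.378}
      us_uk: {base: 0.292, low: 0.216, high: 0.372}
    rrr_chemo: {base: 0.74, low: 0.47, high: 0.87}
costs:
  assay: {base: 350000, low: 262500, high: 437500}
  chemo_drugs: {base: 561813, low: 280907, high: 1500000}
  adverse_events: {base: 170831, low: 85416, high: 256247}
  time_transport: {base: 68500, low: 34250, high: 102750}
  surveillance_annual: {base: 25416, low: 12708, high: 38124}
  recurrence_annual: {base: 2405924, low: 1202962, high: 3608886}
utilities:
  u_recurrence_free: {base: 0.98, low: 0.78, high: 1.00}
  u_progression: {base: 0.30, low: 0.24, high: 0.36}
  chemo_qaly_tariff: {base: 0.53, low: 0.43, high: 0.64}
settings:
  start_age: {base: 49.8, low: 35.0, high: 75.0}
  discount_rate: {base: 0.03, low: 0.01, high: 0.05}
  post_recurrence_mortality_annual: {base: 0.40, low: 0.20, high: 0.60}
  # fatal chemotherapy toxicity: no published range; +/-100% broad-range convention
  fatal_toxicity_risk: {base: 0.002, low: 0.0, high: 0.004}
  max_age: 110.0
  cycle_length: 1.0
  recurrence_hazard_mode: lifetime
  half_cycle_correction: true
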