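# Base-case parameter file: published 6-month transition probabilities for
# severe lupus nephritis (class III/IV +/- V) treatment pathways, with the
# ranges used in sensitivity analysis.  Estimates are PERCENTAGES, exactly as
# the source table prints them; the loader converts to proportions.
#
# Utilities and per-state costs are intentionally absent here: the published
# supplementary tables are not redistributable, so the loader falls back to
# the packaged synthetic tables that satisfy every constraint stated in the
# main text (see lncea.synthetic_data).

transitions:
  induction_cr:
    CYC: {estimate: 40.84, range: [21.74, 66.67], source: "head-to-head induction cohort"}
    MMF: {estimate: 31.37, range: [25.00, 54.00], source: "head-to-head induction cohort"}
    RTX: {estimate: 45.78, range: [14.20, 72.70], source: "head-to-head induction cohort"}
  induction_esrd: {estimate: 0.80, range: [0.71, 0.84], source: "registry"}
  induction_death: {estimate: 0.80, range: [0.48, 1.87], source: "registry"}
  failure_esrd: {estimate: 2.48, range: [0.81, 8.00], source: "refractory LN cohort"}
  failure_death: {estimate: 2.83, range: [2.14, 3.64], source: "refractory LN cohort"}
  maintenance:
    CYC:
      relapse: {estimate: 5.00, range: [3.30, 7.73], source: "maintenance meta-analysis"}
      esrd: {estimate: 0.45, range: [0.23, 0.96], source: "maintenance meta-analysis"}
      death: {estimate: 1.84, range: [0.33, 13.08], source: "maintenance meta-analysis"}
    AZA:
      relapse: {estimate: 3.64, range: [2.34, 5.87], source: "maintenance meta-analysis"}
      esrd: {estimate: 0.30, range: [0.06, 1.60], source: "maintenance meta-analysis"}
      death: {estimate: 0.25, range: [0.04, 1.57], source: "maintenance meta-analysis"}
    MMF:
      relapse: {estimate: 1.85, range: [1.22, 2.86], source: "maintenance meta-analysis"}
      esrd: {estimate: 0.12, range: [0.02, 0.63], source: "maintenance meta-analysis"}
      death: {estimate: 0.43, range: [0.07, 2.85], source: "maintenance meta-analysis"}
  dialysis_to_kt: {estimate: 0.85, range: [0.36, 2.01], source: "renal replacement registry"}
  dialysis_death: {estimate: 4.29, range: [1.00, 7.47], source: "renal replacement registry"}
  kt_death: {estimate: 0.29, range: [0.19, 0.37], source: "renal replacement registry"}

economics:
  cycle_length: 0.5
  discount_per_cycle: 0.015
  discount_low: 0.0
  discount_high: 0.03
  horizon_cycles: 60
  cohort_size: 1000
  wtp_1x: 10319.0
  wtp_3x: 30957.0
  cny_per_usd: 6.87
  psa_draws: 1000
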