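# Baseline inputs: ustekinumab vs vedolizumab, TNF-alpha-inhibitor failure
# population.  All published values verbatim (2016 EUR, SEK->EUR 0.1057);
# paths listed under provenance_synthetic are stand-ins, not published values.
schema_version: 1
population:
  name: tnf_failure
  mean_age: 37.3
  mean_weight_kg: 69.8
  proportion_female: 0.572
  weight_bands:       # printed bands sum to 100.1%; renormalised at load
    under_55: 0.229
    from_55_to_84: 0.588
    over_85: 0.184
  gamma_mod_sev_remainder: 0.060
intervention: ustekinumab
comparator: vedolizumab
treatments:
  ustekinumab:
    schedule:
      first_doses:
        - {week: 0, dose_mg: weight_based, route: IV}
      first_assessment_week: 6
      first_duration_weeks: 8
      second_doses:
        - {week: 8, dose_mg: 90, route: SC}
      second_assessment_week: 16
    weight_based_doses_mg:
      under_55: 260
      from_55_to_84: 390
      over_85: 520
    maintenance: {dose_mg: 90, interval_weeks: 12, route: SC}
    efficacy:
      beta_response: 0.337
      alpha_remission: 0.185
      second_dose_response: 0.411
      second_dose_remission: 0.184
    efficacy_cdai70:
      beta_response: 0.397
      alpha_remission: 0.185
      second_dose_response: 0.471
      second_dose_remission: 0.184
    discontinuation_cycle_prob_standard: 0.106
    discontinuation_cycle_prob_escalated: 0.114
    escalation_cycle_prob: 0.02
    escalation_cost_multiplier: 1.5
    convergence_cycles: 26
  vedolizumab:
    schedule:
      first_doses:
        - {week: 0, dose_mg: 300, route: IV}
        - {week: 2, dose_mg: 300, route: IV}
        - {week: 6, dose_mg: 300, route: IV}
      first_assessment_week: 10
      first_duration_weeks: 10
      second_doses:
        - {week: 10, dose_mg: 300, route: IV}
      second_assessment_week: 14
    maintenance: {dose_mg: 300, interval_weeks: 8, route: IV}
    efficacy:
      beta_response: 0.327
      alpha_remission: 0.129
      second_dose_response: 0.160
      second_dose_remission: 0.068
    efficacy_cdai70:
      beta_response: 0.387
      alpha_remission: 0.129
      second_dose_response: 0.220
      second_dose_remission: 0.068
    discontinuation_cycle_prob_standard: 0.377
    discontinuation_cycle_prob_escalated: 0.312
    escalation_cycle_prob: 0.02
    escalation_cost_multiplier: 2.0
    convergence_cycles: 13
costs:
  currency: EUR2016
  sek_to_eur: 0.1057
  drug_packs:
    ustekinumab: {pack_mg: 90, price: 3546}
    adalimumab: {pack_mg: 40, price: 533}
    vedolizumab: {pack_mg: 300, price: 2334}
  iv_admin: 257
  sc_inhospital_admin: 124
  state_direct_2wk:
    remission: 26
    mild: 69
    moderate_severe: 108
    surgery: 7123
  state_indirect_2wk:
    remission: 79
    mild: 281
    moderate_severe: 374
    surgery: 1326
  ae_unit_costs:
    serious_infection: 7500
    tuberculosis: 9500
    lymphoma: 32000
    hypersensitivity: 400
    skin_reaction: 120
  surgery_complication_cost: 8000
  concomitant_soc_fraction: 0.5
  soc_drug_cost_2wk: 45
utilities:
  state_utilities:
    remission: 0.80
    mild: 0.68
    moderate_severe: 0.55
    surgery: 0.55
  ae_disutilities:
    serious_infection: -0.52
    tuberculosis: -0.55
    lymphoma: -0.20
    hypersensitivity: -0.11
    skin_reaction: -0.03
  ae_cycle_rates:
    ustekinumab:
      serious_infection: 0.0034
      tuberculosis: 0.0
      lymphoma: 0.0
      hypersensitivity: 0.0001
      skin_reaction: 0.0075
    vedolizumab:
      serious_infection: 0.0032
      tuberculosis: 0.0
      lymphoma: 0.0
      hypersensitivity: 0.0
      skin_reaction: 0.0059
  alternative_sets:
    bodger: {remission: 0.82, mild: 0.73, moderate_severe: 0.53, surgery: 0.53}
    sf36: {remission: 0.79, mild: 0.70, moderate_severe: 0.59, surgery: 0.59}
    cdai_mapped: {remission: 0.84, mild: 0.66, moderate_severe: 0.51, surgery: 0.51}
settings:
  cycle_length_weeks: 2
  horizon_years: 60
  treatment_duration_years: 2
  discount_rate_costs: 0.03
  discount_rate_effects: 0.03
  induction_surgery_prob: 0.02
  annual_surgery_prob: 0.07
  response_criterion: CDAI100
  include_indirect_costs: true
  include_ae_effects: true
  allow_dose_escalation: true
  half_cycle_correction: false
  wtp_reference: 63000
  utility_set: base
provenance_synthetic:
  - costs.ae_unit_costs
  - costs.surgery_complication_cost
  - costs.soc_drug_cost_2wk
  - treatments.*.escalation_cost_multiplier
  - treatments.*.convergence_cycles
  - treatments.*.efficacy_cdai70
  - utilities.alternative_sets
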