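"""Fixture fidelity (every packaged value equals its printed source),
validation totality, and serialisation round-trips."""

import importlib.resources

import pytest
import yaml

from cdcea import (
    InputValidationError,
    SchemaError,
    load_model_inputs,
    save_model_inputs,
    paper_baseline_inputs,
)
from cdcea.parameters import model_inputs_to_dict


def _raw_fixture(name):
    ref = importlib.resources.files("cdcea.data") / name
    return yaml.safe_load(ref.read_text())


# ---------------------------------------------------------------------------
# published-value fidelity, field by field
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "fixture,treatment,field,expected",
    [
        # induction response/remission rates, first and second dose
        ("conventional_care.yaml", "ustekinumab", "beta_response", 0.555),
        ("conventional_care.yaml", "ustekinumab", "alpha_remission", 0.349),
        ("conventional_care.yaml", "ustekinumab", "second_dose_response", 0.649),
        ("conventional_care.yaml", "ustekinumab", "second_dose_remission", 0.449),
        ("conventional_care.yaml", "adalimumab", "beta_response", 0.548),
        ("conventional_care.yaml", "adalimumab", "alpha_remission", 0.456),
        ("conventional_care.yaml", "adalimumab", "second_dose_response", 0.430),
        ("conventional_care.yaml", "adalimumab", "second_dose_remission", 0.280),
        ("tnf_failure.yaml", "ustekinumab", "beta_response", 0.337),
        ("tnf_failure.yaml", "ustekinumab", "alpha_remission", 0.185),
        ("tnf_failure.yaml", "ustekinumab", "second_dose_response", 0.411),
        ("tnf_failure.yaml", "ustekinumab", "second_dose_remission", 0.184),
        ("tnf_failure.yaml", "vedolizumab", "beta_response", 0.327),
        ("tnf_failure.yaml", "vedolizumab", "alpha_remission", 0.129),
        ("tnf_failure.yaml", "vedolizumab", "second_dose_response", 0.160),
        ("tnf_failure.yaml", "vedolizumab", "second_dose_remission", 0.068),
    ],
)
def test_induction_efficacy_values(fixture, treatment, field, expected):
    raw = _raw_fixture(fixture)
    assert raw["treatments"][treatment]["efficacy"][field] == expected


@pytest.mark.parametrize(
    "fixture,path,expected",
    [
        # population characteristics
        ("conventional_care.yaml", ("population", "mean_age"), 39.2),
        ("conventional_care.yaml", ("population", "mean_weight_kg"), 73.4),
        ("conventional_care.yaml", ("population", "proportion_female"), 0.529),
        ("conventional_care.yaml", ("population", "weight_bands", "under_55"), 0.194),
        ("conventional_care.yaml", ("population", "weight_bands", "from_55_to_84"), 0.597),
        ("conventional_care.yaml", ("population", "weight_bands", "over_85"), 0.209),
        ("conventional_care.yaml", ("population", "gamma_mod_sev_remainder"), 0.047),
        ("tnf_failure.yaml", ("population", "mean_age"), 37.3),
        ("tnf_failure.yaml", ("population", "mean_weight_kg"), 69.8),
        ("tnf_failure.yaml", ("population", "proportion_female"), 0.572),
        ("tnf_failure.yaml", ("population", "weight_bands", "under_55"), 0.229),
        ("tnf_failure.yaml", ("population", "weight_bands", "from_55_to_84"), 0.588),
        ("tnf_failure.yaml", ("population", "weight_bands", "over_85"), 0.184),
        ("tnf_failure.yaml", ("population", "gamma_mod_sev_remainder"), 0.060),
        # drug pack prices and administration costs (2016 EUR)
        ("conventional_care.yaml", ("costs", "drug_packs", "ustekinumab", "price"), 3546),
        ("conventional_care.yaml", ("costs", "drug_packs", "adalimumab", "price"), 533),
        ("conventional_care.yaml", ("costs", "drug_packs", "vedolizumab", "price"), 2334),
        ("conventional_care.yaml", ("costs", "iv_admin"), 257),
        ("conventional_care.yaml", ("costs", "sc_inhospital_admin"), 124),
        ("conventional_care.yaml", ("costs", "sek_to_eur"), 0.1057),
        ("conventional_care.yaml", ("costs", "concomitant_soc_fraction"), 0.5),
        # two-week health-state costs
        ("conventional_care.yaml", ("costs", "state_direct_2wk", "remission"), 26),
        ("conventional_care.yaml", ("costs", "state_direct_2wk", "mild"), 69),
        ("conventional_care.yaml", ("costs", "state_direct_2wk", "moderate_severe"), 108),
        ("conventional_care.yaml", ("costs", "state_direct_2wk", "surgery"), 7123),
        ("conventional_care.yaml", ("costs", "state_indirect_2wk", "remission"), 79),
        ("conventional_care.yaml", ("costs", "state_indirect_2wk", "mild"), 281),
        ("conventional_care.yaml", ("costs", "state_indirect_2wk", "moderate_severe"), 374),
        ("conventional_care.yaml", ("costs", "state_indirect_2wk", "surgery"), 1326),
        # utilities and AE disutilities
        ("conventional_care.yaml", ("utilities", "state_utilities", "remission"), 0.80),
        ("conventional_care.yaml", ("utilities", "state_utilities", "mild"), 0.68),
        ("conventional_care.yaml", ("utilities", "state_utilities", "moderate_severe"), 0.55),
        ("conventional_care.yaml", ("utilities", "state_utilities", "surgery"), 0.55),
        ("conventional_care.yaml", ("utilities", "ae_disutilities", "serious_infection"), -0.52),
        ("conventional_care.yaml", ("utilities", "ae_disutilities", "tuberculosis"), -0.55),
        ("conventional_care.yaml", ("utilities", "ae_disutilities", "lymphoma"), -0.20),
        ("conventional_care.yaml", ("utilities", "ae_disutilities", "hypersensitivity"), -0.11),
        ("conventional_care.yaml", ("utilities", "ae_disutilities", "skin_reaction"), -0.03),
        # AE cycle rates
        ("conventional_care.yaml", ("utilities", "ae_cycle_rates", "ustekinumab", "serious_infection"), 0.0034),
        ("conventional_care.yaml", ("utilities", "ae_cycle_rates", "ustekinumab", "skin_reaction"), 0.0075),
        ("conventional_care.yaml", ("utilities", "ae_cycle_rates", "adalimumab", "serious_infection"), 0.0032),
        ("conventional_care.yaml", ("utilities", "ae_cycle_rates", "adalimumab", "skin_reaction"), 0.1037),
        ("tnf_failure.yaml", ("utilities", "ae_cycle_rates", "vedolizumab", "serious_infection"), 0.0032),
        ("tnf_failure.yaml", ("utilities", "ae_cycle_rates", "vedolizumab", "skin_reaction"), 0.0059),
        # discontinuation / escalation cycle probabilities
        ("conventional_care.yaml", ("treatments", "ustekinumab", "discontinuation_cycle_prob_standard"), 0.106),
        ("conventional_care.yaml", ("treatments", "ustekinumab", "discontinuation_cycle_prob_escalated"), 0.114),
        ("conventional_care.yaml", ("treatments", "adalimumab", "discontinuation_cycle_prob_standard"), 0.081),
        ("tnf_failure.yaml", ("treatments", "vedolizumab", "discontinuation_cycle_prob_standard"), 0.377),
        ("tnf_failure.yaml", ("treatments", "vedolizumab", "discontinuation_cycle_prob_escalated"), 0.312),
        ("conventional_care.yaml", ("treatments", "ustekinumab", "escalation_cycle_prob"), 0.02),
        ("conventional_care.yaml", ("treatments", "adalimumab", "escalation_cycle_prob"), 0.03),
        ("tnf_failure.yaml", ("treatments", "vedolizumab", "escalation_cycle_prob"), 0.02),
        # structural settings
        ("conventional_care.yaml", ("settings", "cycle_length_weeks"), 2),
        ("conventional_care.yaml", ("settings", "horizon_years"), 60),
        ("conventional_care.yaml", ("settings", "treatment_duration_years"), 2),
        ("conventional_care.yaml", ("settings", "discount_rate_costs"), 0.03),
        ("conventional_care.yaml", ("settings", "discount_rate_effects"), 0.03),
        ("conventional_care.yaml", ("settings", "induction_surgery_prob"), 0.02),
        ("conventional_care.yaml", ("settings", "annual_surgery_prob"), 0.07),
        ("conventional_care.yaml", ("settings", "wtp_reference"), 63000),
        # dosing schedules
        ("conventional_care.yaml", ("treatments", "ustekinumab", "weight_based_doses_mg", "under_55"), 260),
        ("conventional_care.yaml", ("treatments", "ustekinumab", "weight_based_doses_mg", "from_55_to_84"), 390),
        ("conventional_care.yaml", ("treatments", "ustekinumab", "weight_based_doses_mg", "over_85"), 520),
        ("conventional_care.yaml", ("treatments", "ustekinumab", "maintenance", "dose_mg"), 90),
        ("conventional_care.yaml", ("treatments", "ustekinumab", "maintenance", "interval_weeks"), 12),
        ("conventional_care.yaml", ("treatments", "adalimumab", "maintenance", "dose_mg"), 40),
        ("conventional_care.yaml", ("treatments", "adalimumab", "maintenance", "interval_weeks"), 2),
        ("tnf_failure.yaml", ("treatments", "vedolizumab", "maintenance", "dose_mg"), 300),
        ("tnf_failure.yaml", ("treatments", "vedolizumab", "maintenance", "interval_weeks"), 8),
        ("conventional_care.yaml", ("treatments", "ustekinumab", "schedule", "first_assessment_week"), 6),
        ("conventional_care.yaml", ("treatments", "ustekinumab", "schedule", "second_assessment_week"), 16),
        ("conventional_care.yaml", ("treatments", "ustekinumab", "schedule", "first_duration_weeks"), 8),
        ("conventional_care.yaml", ("treatments", "adalimumab", "schedule", "first_assessment_week"), 4),
        ("conventional_care.yaml", ("treatments", "adalimumab", "schedule", "first_duration_weeks"), 4),
        ("conventional_care.yaml", ("treatments", "adalimumab", "schedule", "second_assessment_week"), 12),
        ("tnf_failure.yaml", ("treatments", "vedolizumab", "schedule", "first_assessment_week"), 10),
        ("tnf_failure.yaml", ("treatments", "vedolizumab", "schedule", "first_duration_weeks"), 10),
        ("tnf_failure.yaml", ("treatments", "vedolizumab", "schedule", "second_assessment_week"), 14),
    ],
)
def test_packaged_value_matches_print(fixture, path, expected):
    node = _raw_fixture(fixture)
    for key in path:
        node = node[key]
    assert node == expected


def test_ustekinumab_iv_induction_then_sc():
    raw = _raw_fixture("conventional_care.yaml")
    sched = raw["treatments"]["ustekinumab"]["schedule"]
    assert sched["first_doses"] == [
        {"week": 0, "dose_mg": "weight_based", "route": "IV"}
    ]
    assert sched["second_doses"] == [{"week": 8, "dose_mg": 90, "route": "SC"}]


def test_vedolizumab_three_iv_induction_doses():
    raw = _raw_fixture("tnf_failure.yaml")
    sched = raw["treatments"]["vedolizumab"]["schedule"]
    assert [d["week"] for d in sched["first_doses"]] == [0, 2, 6]
    assert all(d["route"] == "IV" for d in sched["first_doses"])


# ---------------------------------------------------------------------------
# loading, validation, round-trips
# ---------------------------------------------------------------------------


def test_baseline_loads_with_drug_prices(conv_inputs):
    assert conv_inputs.costs.drug_packs["ustekinumab"]["price"] == 3546
    assert conv_inputs.costs.drug_packs["adalimumab"]["price"] == 533
    assert conv_inputs.population.gamma_mod_sev_remainder == 0.047


def test_tnf_baseline_gamma_and_efficacy(tnf_inputs):
    assert tnf_inputs.population.gamma_mod_sev_remainder == 0.060
    assert tnf_inputs.efficacy["ustekinumab"].beta_response == 0.337
    assert tnf_inputs.efficacy["vedolizumab"].alpha_remission == 0.129


def test_unpublished_inputs_flagged_synthetic(conv_inputs):
    assert "unpublished.*" in conv_inputs.provenance_synthetic


def test_tnf_weight_bands_renormalised(tnf_inputs):
    # printed bands sum to 100.1%; loader renormalises to an exact simplex
    assert abs(sum(tnf_inputs.population.weight_bands.values()) - 1.0) < 1e-12


def test_unknown_population_rejected():
    with pytest.raises(KeyError):
        paper_baseline_inputs("nonexistent_population")


def test_weight_band_sum_violation_named():
    raw = _raw_fixture("conventional_care.yaml")
    raw["population"]["weight_bands"] = {
        "under_55": 0.5, "from_55_to_84": 0.6, "over_85": 0.1,
    }
    with pytest.raises(InputValidationError, match="weight_bands"):
        load_model_inputs(raw)


def test_missing_field_names_path():
    raw = _raw_fixture("conventional_care.yaml")
    del raw["costs"]["iv_admin"]
    with pytest.raises(SchemaError, match="costs.iv_admin"):
        load_model_inputs(raw)


@pytest.mark.parametrize(
    "mutate,fragment",
    [
        (lambda d: d["utilities"]["state_utilities"].__setitem__("mild", 1.4),
         "state_utilities"),
        (lambda d: d["treatments"]["ustekinumab"].__setitem__(
            "escalation_cycle_prob", -0.1), "escalation_cycle_prob"),
        (lambda d: d["treatments"]["ustekinumab"]["efficacy"].__setitem__(
            "alpha_remission", 0.9), "remission"),
        (lambda d: d["settings"].__setitem__("horizon_years", 1), "horizon"),
        (lambda d: d["costs"]["state_direct_2wk"].__setitem__("mild", -5),
         "state_direct_2wk"),
    ],
)
def test_single_field_corruption_rejected_with_name(mutate, fragment):
    raw = _raw_fixture("conventional_care.yaml")
    mutate(raw)
    with pytest.raises(InputValidationError, match=fragment):
        load_model_inputs(raw)


def test_validation_reports_all_failures_not_just_first():
    raw = _raw_fixture("conventional_care.yaml")
    raw["utilities"]["state_utilities"]["mild"] = 1.4
    raw["costs"]["state_direct_2wk"]["mild"] = -5
    with pytest.raises(InputValidationError) as exc:
        load_model_inputs(raw)
    assert len(exc.value.errors) >= 2


def test_round_trip_identity(tmp_path, conv_inputs):
    path = tmp_path / "inputs.yaml"
    save_model_inputs(conv_inputs, path)
    reloaded = load_model_inputs(path)
    assert model_inputs_to_dict(reloaded) == model_inputs_to_dict(conv_inputs)
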