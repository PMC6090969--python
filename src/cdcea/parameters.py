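"""Domain types, input validation and packaged baseline inputs.

The model is parameterised by a :class:`ModelInputs` bundle: one population,
two treatment strategies (intervention and comparator), unit costs, health
state utilities, structural settings, and the inputs that are not publicly
printed anywhere (standard-of-care transition matrix, post-surgery
distribution, background mortality, end-of-maintenance target distributions,
surgical complication probability).  The latter group carries ``synthetic``
provenance and is produced by :mod:`cdcea.synthetic`.

Two baseline input documents are packaged: ``conventional_care.yaml``
(ustekinumab vs adalimumab in patients who failed conventional care) and
``tnf_failure.yaml`` (ustekinumab vs vedolizumab in patients who failed
TNF-alpha-inhibitor therapy).  All published values in them are shipped
verbatim in 2016 EUR (SEK converted at 0.1057).
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import numpy as np
import yaml

from .states import CDAI_STATES

__all__ = [
    "SchemaError",
    "InputValidationError",
    "Population",
    "InductionEfficacy",
    "DoseEvent",
    "TreatmentSpec",
    "CostInputs",
    "UtilityInputs",
    "StructuralSettings",
    "UnpublishedInputs",
    "ModelInputs",
    "load_model_inputs",
    "save_model_inputs",
    "paper_baseline_inputs",
    "POPULATIONS",
]

POPULATIONS = ("conventional_care_failure", "tnf_failure")

WEIGHT_BANDS = ("under_55", "from_55_to_84", "over_85")

AE_TYPES = (
    "serious_infection",
    "tuberculosis",
    "lymphoma",
    "hypersensitivity",
    "skin_reaction",
)


class SchemaError(ValueError):
    """A required section or field is missing from an input document."""


class InputValidationError(ValueError):
    """One or more invariant violations; ``errors`` lists all of them."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "invalid model inputs:\n" + "\n".join(f"  - {e}" for e in errors)
        )


def _frac(x: float) -> bool:
    return 0.0 <= x <= 1.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """Cohort characteristics of one analysis population."""

    name: str
    mean_age: float
    mean_weight_kg: float
    proportion_female: float
    weight_bands: dict[str, float]
    #: fraction gamma of responders who remain moderate-to-severe after
    #: induction response.
    gamma_mod_sev_remainder: float

    def validate(self, path: str = "population") -> list[str]:
        errs = []
        if self.name not in POPULATIONS:
            errs.append(f"{path}.name: unknown population {self.name!r}")
        if not _frac(self.proportion_female):
            errs.append(f"{path}.proportion_female: not in [0,1]")
        if not _frac(self.gamma_mod_sev_remainder):
            errs.append(f"{path}.gamma_mod_sev_remainder: not in [0,1]")
        if set(self.weight_bands) != set(WEIGHT_BANDS):
            errs.append(f"{path}.weight_bands: keys must be {WEIGHT_BANDS}")
        else:
            total = sum(self.weight_bands.values())
            if abs(total - 1.0) > 1e-9:
                errs.append(
                    f"{path}.weight_bands: sum != 1 (got {total:.6f})"
                )
            if any(not _frac(v) for v in self.weight_bands.values()):
                errs.append(f"{path}.weight_bands: fraction not in [0,1]")
        if self.mean_age <= 0:
            errs.append(f"{path}.mean_age: must be positive")
        return errs


@dataclass
class InductionEfficacy:
    """Induction response/remission probabilities for one treatment.

    ``alpha_remission`` (alpha) and ``beta_response`` (beta) refer to the
    first induction dose; the second-dose pair applies to first-dose
    non-responders who receive an additional dose.  Remitters are a subset
    of responders, so alpha <= beta at each stage.
    """

    alpha_remission: float
    beta_response: float
    second_dose_remission: float
    second_dose_response: float

    def validate(self, path: str = "efficacy") -> list[str]:
        errs = []
        for a, b, stage in (
            (self.alpha_remission, self.beta_response, "first"),
            (self.second_dose_remission, self.second_dose_response, "second"),
        ):
            if not (_frac(a) and _frac(b)):
                errs.append(f"{path}.{stage}: probabilities not in [0,1]")
            elif a > b + 1e-12:
                errs.append(
                    f"{path}.{stage}: remission {a} exceeds response {b}"
                )
        return errs


@dataclass
class DoseEvent:
    """One administration occasion in the induction schedule.

    ``dose_mg`` is a number, or the string ``"weight_based"`` for the
    weight-banded ustekinumab IV induction dose.
    """

    week: float
    dose_mg: float | str
    route: str  # "IV" or "SC"

    def validate(self, path: str) -> list[str]:
        errs = []
        if self.route not in ("IV", "SC"):
            errs.append(f"{path}.route: must be IV or SC, got {self.route!r}")
        if self.week < 0:
            errs.append(f"{path}.week: negative")
        if isinstance(self.dose_mg, str) and self.dose_mg != "weight_based":
            errs.append(f"{path}.dose_mg: invalid marker {self.dose_mg!r}")
        if isinstance(self.dose_mg, (int, float)) and self.dose_mg <= 0:
            errs.append(f"{path}.dose_mg: must be positive")
        return errs


@dataclass
class TreatmentSpec:
    """Dosing schedule and maintenance behaviour of one biologic."""

    name: str
    first_doses: list[DoseEvent]
    first_assessment_week: float
    #: induction duration (weeks) for first-dose responders; cost/utility
    #: accrual span for that branch of the tree.
    first_duration_weeks: float
    second_doses: list[DoseEvent]
    second_assessment_week: float
    maintenance_dose_mg: float
    maintenance_interval_weeks: float
    maintenance_route: str
    #: weight-banded first induction dose in mg, keyed like
    #: ``Population.weight_bands``; only for weight_based first doses.
    weight_based_doses_mg: dict[str, float] | None
    discontinuation_cycle_prob_standard: float
    discontinuation_cycle_prob_escalated: float
    escalation_cycle_prob: float
    escalation_cost_multiplier: float
    #: cycles over which the calibrated matrix blends into the SoC matrix
    #: after treatment stops (gradual post-treatment efficacy decline).
    convergence_cycles: int

    def validate(self, path: str) -> list[str]:
        errs = []
        for p, nm in (
            (self.discontinuation_cycle_prob_standard, "discontinuation_cycle_prob_standard"),
            (self.discontinuation_cycle_prob_escalated, "discontinuation_cycle_prob_escalated"),
            (self.escalation_cycle_prob, "escalation_cycle_prob"),
        ):
            if not _frac(p):
                errs.append(f"{path}.{nm}: not in [0,1]")
        if self.maintenance_interval_weeks <= 0:
            errs.append(f"{path}.maintenance_interval_weeks: must be positive")
        if self.maintenance_route not in ("IV", "SC"):
            errs.append(f"{path}.maintenance_route: must be IV or SC")
        if self.escalation_cost_multiplier < 1.0:
            errs.append(f"{path}.escalation_cost_multiplier: must be >= 1")
        if self.convergence_cycles < 0:
            errs.append(f"{path}.convergence_cycles: must be >= 0")
        if self.second_assessment_week < self.first_assessment_week:
            errs.append(f"{path}: second assessment precedes the first")
        needs_weight = any(d.dose_mg == "weight_based" for d in self.first_doses)
        if needs_weight and not self.weight_based_doses_mg:
            errs.append(f"{path}.weight_based_doses_mg: required for weight-based dosing")
        if self.weight_based_doses_mg is not None and set(
            self.weight_based_doses_mg
        ) != set(WEIGHT_BANDS):
            errs.append(f"{path}.weight_based_doses_mg: keys must be {WEIGHT_BANDS}")
        for i, d in enumerate(self.first_doses):
            errs += d.validate(f"{path}.first_doses[{i}]")
        for i, d in enumerate(self.second_doses):
            errs += d.validate(f"{path}.second_doses[{i}]")
        return errs


@dataclass
class CostInputs:
    """Unit costs (2016 EUR) and two-week health-state costs."""

    currency: str
    sek_to_eur: float
    #: per treatment: {"pack_mg": .., "price": ..}; weight-based induction
    #: doses are costed pro rata per mg from the pack price.
    drug_packs: dict[str, dict[str, float]]
    iv_admin: float
    sc_inhospital_admin: float
    state_direct_2wk: dict[str, float]
    state_indirect_2wk: dict[str, float]
    ae_unit_costs: dict[str, float]
    surgery_complication_cost: float
    #: fraction of on-biologic patients receiving concomitant SoC therapy.
    concomitant_soc_fraction: float
    soc_drug_cost_2wk: float

    def validate(self, path: str = "costs") -> list[str]:
        errs = []
        state_keys = set(CDAI_STATES) | {"surgery"}
        for nm, d in (
            ("state_direct_2wk", self.state_direct_2wk),
            ("state_indirect_2wk", self.state_indirect_2wk),
        ):
            if set(d) != state_keys:
                errs.append(f"{path}.{nm}: keys must be {sorted(state_keys)}")
            elif any(v < 0 for v in d.values()):
                errs.append(f"{path}.{nm}: negative cost")
        for nm, v in (
            ("iv_admin", self.iv_admin),
            ("sc_inhospital_admin", self.sc_inhospital_admin),
            ("surgery_complication_cost", self.surgery_complication_cost),
            ("soc_drug_cost_2wk", self.soc_drug_cost_2wk),
        ):
            if v < 0:
                errs.append(f"{path}.{nm}: negative cost")
        if any(v < 0 for v in self.ae_unit_costs.values()):
            errs.append(f"{path}.ae_unit_costs: negative cost")
        for t, pk in self.drug_packs.items():
            if pk.get("pack_mg", 0) <= 0 or pk.get("price", -1) < 0:
                errs.append(f"{path}.drug_packs.{t}: invalid pack")
        if not _frac(self.concomitant_soc_fraction):
            errs.append(f"{path}.concomitant_soc_fraction: not in [0,1]")
        if self.sek_to_eur <= 0:
            errs.append(f"{path}.sek_to_eur: must be positive")
        return errs


@dataclass
class UtilityInputs:
    """Health-state utilities, AE disutilities and AE cycle rates."""

    state_utilities: dict[str, float]
    ae_disutilities: dict[str, float]
    #: per treatment, per AE type, probability of the event per 2-week cycle.
    ae_cycle_rates: dict[str, dict[str, float]]
    #: optional named alternative utility sets for scenario analyses.
    alternative_sets: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self, path: str = "utilities") -> list[str]:
        errs = []
        state_keys = set(CDAI_STATES) | {"surgery"}
        for name, uset in {"state_utilities": self.state_utilities, **{
            f"alternative_sets.{k}": v for k, v in self.alternative_sets.items()
        }}.items():
            if set(uset) != state_keys:
                errs.append(f"{path}.{name}: keys must be {sorted(state_keys)}")
            elif any(not _frac(u) for u in uset.values()):
                errs.append(f"{path}.{name}: utility not in [0,1]")
        for ae, d in self.ae_disutilities.items():
            if not (-1.0 <= d <= 0.0):
                errs.append(f"{path}.ae_disutilities.{ae}: must be in [-1,0]")
        for t, rates in self.ae_cycle_rates.items():
            for ae, r in rates.items():
                if not _frac(r):
                    errs.append(f"{path}.ae_cycle_rates.{t}.{ae}: not in [0,1]")
        return errs


@dataclass
class StructuralSettings:
    """Structural model settings (cycle length, horizon, discounting...)."""

    cycle_length_weeks: float = 2.0
    horizon_years: float = 60.0
    treatment_duration_years: float = 2.0
    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    induction_surgery_prob: float = 0.02
    annual_surgery_prob: float = 0.07
    response_criterion: str = "CDAI100"
    include_indirect_costs: bool = True
    include_ae_effects: bool = True
    allow_dose_escalation: bool = True
    half_cycle_correction: bool = False
    wtp_reference: float = 63000.0
    utility_set: str = "base"

    def validate(self, path: str = "settings") -> list[str]:
        errs = []
        if self.horizon_years < self.treatment_duration_years:
            errs.append(f"{path}.horizon_years: shorter than treatment duration")
        for nm, v in (
            ("induction_surgery_prob", self.induction_surgery_prob),
            ("annual_surgery_prob", self.annual_surgery_prob),
        ):
            if not _frac(v):
                errs.append(f"{path}.{nm}: not in [0,1]")
        for nm, v in (
            ("discount_rate_costs", self.discount_rate_costs),
            ("discount_rate_effects", self.discount_rate_effects),
        ):
            if v < 0:
                errs.append(f"{path}.{nm}: negative rate")
        if self.response_criterion not in ("CDAI100", "CDAI70"):
            errs.append(f"{path}.response_criterion: must be CDAI100 or CDAI70")
        if self.cycle_length_weeks <= 0:
            errs.append(f"{path}.cycle_length_weeks: must be positive")
        if self.wtp_reference < 0:
            errs.append(f"{path}.wtp_reference: negative")
        return errs

    @property
    def cycles_per_year(self) -> float:
        return 52.0 / self.cycle_length_weeks

    @property
    def horizon_cycles(self) -> int:
        return int(round(self.horizon_years * self.cycles_per_year))

    @property
    def treatment_duration_weeks(self) -> float:
        return self.treatment_duration_years * 52.0


@dataclass
class UnpublishedInputs:
    """Inputs the model needs but no public source prints.

    Supplied with ``synthetic`` provenance by :mod:`cdcea.synthetic` unless a
    user provides their own values.
    """

    #: 3x3 row-stochastic matrix over CDAI states, per 2-week cycle.
    soc_transition_matrix: np.ndarray
    #: distribution over CDAI states on leaving the surgery state.
    post_surgery_distribution: np.ndarray
    #: per-cycle death probability indexed by integer age.
    mortality_table: dict[int, float]
    #: per treatment: end-of-maintenance target fractions {remission, mild}.
    maintenance_targets: dict[str, dict[str, float]]
    surgery_complication_prob: float
    #: optional pre-calibrated per-treatment biologic matrices; when set the
    #: pipeline uses them directly instead of calibrating (used by the PSA).
    biologic_matrices: dict[str, np.ndarray] | None = None

    def validate(self, path: str = "unpublished") -> list[str]:
        errs = []
        m = np.asarray(self.soc_transition_matrix, dtype=float)
        if m.shape != (3, 3):
            errs.append(f"{path}.soc_transition_matrix: shape must be 3x3")
        else:
            if (m < -1e-12).any() or (m > 1 + 1e-12).any():
                errs.append(f"{path}.soc_transition_matrix: entries outside [0,1]")
            if np.abs(m.sum(axis=1) - 1).max() > 1e-9:
                errs.append(f"{path}.soc_transition_matrix: rows must sum to 1")
        d = np.asarray(self.post_surgery_distribution, dtype=float)
        if d.shape != (3,):
            errs.append(f"{path}.post_surgery_distribution: length must be 3")
        elif (d < -1e-12).any() or abs(d.sum() - 1) > 1e-9:
            errs.append(f"{path}.post_surgery_distribution: not a distribution")
        ages = sorted(self.mortality_table)
        qs = [self.mortality_table[a] for a in ages]
        if any(not _frac(q) for q in qs):
            errs.append(f"{path}.mortality_table: probability not in [0,1]")
        if any(b < a - 1e-15 for a, b in zip(qs, qs[1:])):
            errs.append(f"{path}.mortality_table: not non-decreasing in age")
        for t, tg in self.maintenance_targets.items():
            r, mi = tg.get("remission", -1), tg.get("mild", -1)
            if not (_frac(r) and _frac(mi) and r + mi <= 1 + 1e-9):
                errs.append(f"{path}.maintenance_targets.{t}: invalid target")
        if not _frac(self.surgery_complication_prob):
            errs.append(f"{path}.surgery_complication_prob: not in [0,1]")
        if self.biologic_matrices is not None:
            for t, bm in self.biologic_matrices.items():
                bm = np.asarray(bm, dtype=float)
                if bm.shape != (3, 3) or np.abs(bm.sum(axis=1) - 1).max() > 1e-9:
                    errs.append(f"{path}.biologic_matrices.{t}: not row-stochastic 3x3")
        return errs


@dataclass
class ModelInputs:
    """Complete parameter set for one population/comparison."""

    population: Population
    intervention: str
    comparator: str
    treatments: dict[str, TreatmentSpec]
    efficacy: dict[str, InductionEfficacy]
    #: optional per-treatment CDAI-70 efficacy sets for the scenario grid.
    efficacy_cdai70: dict[str, InductionEfficacy]
    costs: CostInputs
    utilities: UtilityInputs
    settings: StructuralSettings
    unpublished: UnpublishedInputs
    #: dotted parameter paths whose values are stand-ins, not published ones.
    provenance_synthetic: list[str] = field(default_factory=list)
    schema_version: int = 1

    @property
    def strategies(self) -> tuple[str, str]:
        return (self.intervention, self.comparator)

    def active_efficacy(self, treatment: str) -> InductionEfficacy:
        """Efficacy set selected by the response criterion in settings."""
        if self.settings.response_criterion == "CDAI70":
            if treatment not in self.efficacy_cdai70:
                raise SchemaError(f"no CDAI-70 efficacy set for {treatment!r}")
            return self.efficacy_cdai70[treatment]
        return self.efficacy[treatment]

    def active_utilities(self) -> dict[str, float]:
        """State-utility set selected by ``settings.utility_set``."""
        if self.settings.utility_set == "base":
            return self.utilities.state_utilities
        try:
            return self.utilities.alternative_sets[self.settings.utility_set]
        except KeyError:
            raise SchemaError(
                f"unknown utility set {self.settings.utility_set!r}"
            ) from None

    def validate(self) -> list[str]:
        errs = []
        errs += self.population.validate()
        if self.intervention == self.comparator:
            errs.append("intervention and comparator must differ")
        for role, t in (("intervention", self.intervention),
                        ("comparator", self.comparator)):
            if t not in self.treatments:
                errs.append(f"{role}: no TreatmentSpec for {t!r}")
            if t not in self.efficacy:
                errs.append(f"{role}: no efficacy for {t!r}")
            if t not in self.costs.drug_packs:
                errs.append(f"{role}: no drug pack price for {t!r}")
            if t not in self.utilities.ae_cycle_rates:
                errs.append(f"{role}: no AE cycle rates for {t!r}")
            if t not in self.unpublished.maintenance_targets:
                errs.append(f"{role}: no maintenance target for {t!r}")
        for t, spec in self.treatments.items():
            errs += spec.validate(f"treatments.{t}")
        for t, eff in self.efficacy.items():
            errs += eff.validate(f"efficacy.{t}")
        for t, eff in self.efficacy_cdai70.items():
            errs += eff.validate(f"efficacy_cdai70.{t}")
        errs += self.costs.validate()
        errs += self.utilities.validate()
        errs += self.settings.validate()
        errs += self.unpublished.validate()
        # mortality table must cover the horizon
        if self.unpublished.mortality_table:
            max_age = max(self.unpublished.mortality_table)
            if max_age < self.population.mean_age + self.settings.horizon_years:
                errs.append(
                    "unpublished.mortality_table: does not cover "
                    f"age {self.population.mean_age + self.settings.horizon_years:.0f}"
                )
        return errs

    def check(self) -> "ModelInputs":
        """Raise :class:`InputValidationError` listing every violation."""
        errs = self.validate()
        if errs:
            raise InputValidationError(errs)
        return self


# ---------------------------------------------------------------------------
# (De)serialisation
# ---------------------------------------------------------------------------


def _require(d: Mapping[str, Any], key: str, path: str) -> Any:
    if key not in d:
        raise SchemaError(f"missing field: {path}.{key}" if path else
                          f"missing field: {key}")
    return d[key]


def _dose_events(raw: list[dict], path: str) -> list[DoseEvent]:
    out = []
    for i, r in enumerate(raw):
        out.append(DoseEvent(
            week=float(_require(r, "week", f"{path}[{i}]")),
            dose_mg=_require(r, "dose_mg", f"{path}[{i}]"),
            route=_require(r, "route", f"{path}[{i}]"),
        ))
    return out


def _treatment_from_dict(name: str, raw: Mapping[str, Any]) -> TreatmentSpec:
    p = f"treatments.{name}"
    sched = _require(raw, "schedule", p)
    maint = _require(raw, "maintenance", p)
    wb = raw.get("weight_based_doses_mg")
    return TreatmentSpec(
        name=name,
        first_doses=_dose_events(_require(sched, "first_doses", f"{p}.schedule"), f"{p}.schedule.first_doses"),
        first_assessment_week=float(_require(sched, "first_assessment_week", f"{p}.schedule")),
        first_duration_weeks=float(_require(sched, "first_duration_weeks", f"{p}.schedule")),
        second_doses=_dose_events(_require(sched, "second_doses", f"{p}.schedule"), f"{p}.schedule.second_doses"),
        second_assessment_week=float(_require(sched, "second_assessment_week", f"{p}.schedule")),
        maintenance_dose_mg=float(_require(maint, "dose_mg", f"{p}.maintenance")),
        maintenance_interval_weeks=float(_require(maint, "interval_weeks", f"{p}.maintenance")),
        maintenance_route=str(_require(maint, "route", f"{p}.maintenance")),
        weight_based_doses_mg={k: float(v) for k, v in wb.items()} if wb else None,
        discontinuation_cycle_prob_standard=float(_require(raw, "discontinuation_cycle_prob_standard", p)),
        discontinuation_cycle_prob_escalated=float(_require(raw, "discontinuation_cycle_prob_escalated", p)),
        escalation_cycle_prob=float(_require(raw, "escalation_cycle_prob", p)),
        escalation_cost_multiplier=float(_require(raw, "escalation_cost_multiplier", p)),
        convergence_cycles=int(_require(raw, "convergence_cycles", p)),
    )


def _efficacy_from_dict(raw: Mapping[str, Any], path: str) -> InductionEfficacy:
    return InductionEfficacy(
        alpha_remission=float(_require(raw, "alpha_remission", path)),
        beta_response=float(_require(raw, "beta_response", path)),
        second_dose_remission=float(_require(raw, "second_dose_remission", path)),
        second_dose_response=float(_require(raw, "second_dose_response", path)),
    )


def _unpublished_from_dict(raw: Mapping[str, Any]) -> UnpublishedInputs:
    p = "unpublished"
    bm = raw.get("biologic_matrices")
    return UnpublishedInputs(
        soc_transition_matrix=np.asarray(_require(raw, "soc_transition_matrix", p), dtype=float),
        post_surgery_distribution=np.asarray(_require(raw, "post_surgery_distribution", p), dtype=float),
        mortality_table={int(k): float(v) for k, v in _require(raw, "mortality_table", p).items()},
        maintenance_targets={
            t: {"remission": float(v["remission"]), "mild": float(v["mild"])}
            for t, v in _require(raw, "maintenance_targets", p).items()
        },
        surgery_complication_prob=float(_require(raw, "surgery_complication_prob", p)),
        biologic_matrices=(
            {t: np.asarray(m, dtype=float) for t, m in bm.items()} if bm else None
        ),
    )


def model_inputs_from_dict(doc: Mapping[str, Any]) -> ModelInputs:
    """Build and validate :class:`ModelInputs` from a parsed document.

    Missing unpublished inputs are filled from the synthetic-data defaults
    and flagged with ``synthetic`` provenance.
    """
    pop_raw = _require(doc, "population", "")
    wb = {k: float(v) for k, v in _require(pop_raw, "weight_bands", "population").items()}
    total = sum(wb.values())
    # printed weight bands may round to slightly off 1 (renormalised at load)
    if 1e-9 < abs(total - 1.0) <= 5e-3:
        wb = {k: v / total for k, v in wb.items()}
    population = Population(
        name=str(_require(pop_raw, "name", "population")),
        mean_age=float(_require(pop_raw, "mean_age", "population")),
        mean_weight_kg=float(_require(pop_raw, "mean_weight_kg", "population")),
        proportion_female=float(_require(pop_raw, "proportion_female", "population")),
        weight_bands=wb,
        gamma_mod_sev_remainder=float(_require(pop_raw, "gamma_mod_sev_remainder", "population")),
    )

    treatments_raw = _require(doc, "treatments", "")
    treatments = {t: _treatment_from_dict(t, r) for t, r in treatments_raw.items()}
    efficacy = {
        t: _efficacy_from_dict(_require(r, "efficacy", f"treatments.{t}"), f"treatments.{t}.efficacy")
        for t, r in treatments_raw.items()
    }
    efficacy70 = {
        t: _efficacy_from_dict(r["efficacy_cdai70"], f"treatments.{t}.efficacy_cdai70")
        for t, r in treatments_raw.items()
        if "efficacy_cdai70" in r
    }

    c = _require(doc, "costs", "")
    costs = CostInputs(
        currency=str(c.get("currency", "EUR2016")),
        sek_to_eur=float(_require(c, "sek_to_eur", "costs")),
        drug_packs={t: {"pack_mg": float(v["pack_mg"]), "price": float(v["price"])}
                    for t, v in _require(c, "drug_packs", "costs").items()},
        iv_admin=float(_require(c, "iv_admin", "costs")),
        sc_inhospital_admin=float(_require(c, "sc_inhospital_admin", "costs")),
        state_direct_2wk={k: float(v) for k, v in _require(c, "state_direct_2wk", "costs").items()},
        state_indirect_2wk={k: float(v) for k, v in _require(c, "state_indirect_2wk", "costs").items()},
        ae_unit_costs={k: float(v) for k, v in _require(c, "ae_unit_costs", "costs").items()},
        surgery_complication_cost=float(_require(c, "surgery_complication_cost", "costs")),
        concomitant_soc_fraction=float(_require(c, "concomitant_soc_fraction", "costs")),
        soc_drug_cost_2wk=float(_require(c, "soc_drug_cost_2wk", "costs")),
    )

    u = _require(doc, "utilities", "")
    utilities = UtilityInputs(
        state_utilities={k: float(v) for k, v in _require(u, "state_utilities", "utilities").items()},
        ae_disutilities={k: float(v) for k, v in _require(u, "ae_disutilities", "utilities").items()},
        ae_cycle_rates={t: {k: float(v) for k, v in r.items()}
                        for t, r in _require(u, "ae_cycle_rates", "utilities").items()},
        alternative_sets={n: {k: float(v) for k, v in s.items()}
                          for n, s in u.get("alternative_sets", {}).items()},
    )

    s = doc.get("settings", {})
    settings = StructuralSettings(**{k: v for k, v in s.items()})

    provenance = list(doc.get("provenance_synthetic", []))
    if "unpublished" in doc:
        unpublished = _unpublished_from_dict(doc["unpublished"])
    else:
        # fill from synthetic defaults, flagged as stand-ins
        from .synthetic import default_unpublished_inputs

        unpublished = default_unpublished_inputs(
            population_name=population.name,
            treatments=tuple(treatments),
        )
        provenance.append("unpublished.*")

    mi = ModelInputs(
        population=population,
        intervention=str(_require(doc, "intervention", "")),
        comparator=str(_require(doc, "comparator", "")),
        treatments=treatments,
        efficacy=efficacy,
        efficacy_cdai70=efficacy70,
        costs=costs,
        utilities=utilities,
        settings=settings,
        unpublished=unpublished,
        provenance_synthetic=provenance,
        schema_version=int(doc.get("schema_version", 1)),
    )
    return mi.check()


def model_inputs_to_dict(mi: ModelInputs) -> dict[str, Any]:
    """Serialise :class:`ModelInputs` to a plain document (YAML-safe)."""
    treatments = {}
    for t, spec in mi.treatments.items():
        d = {
            "schedule": {
                "first_doses": [asdict(e) for e in spec.first_doses],
                "first_assessment_week": spec.first_assessment_week,
                "first_duration_weeks": spec.first_duration_weeks,
                "second_doses": [asdict(e) for e in spec.second_doses],
                "second_assessment_week": spec.second_assessment_week,
            },
            "maintenance": {
                "dose_mg": spec.maintenance_dose_mg,
                "interval_weeks": spec.maintenance_interval_weeks,
                "route": spec.maintenance_route,
            },
            "discontinuation_cycle_prob_standard": spec.discontinuation_cycle_prob_standard,
            "discontinuation_cycle_prob_escalated": spec.discontinuation_cycle_prob_escalated,
            "escalation_cycle_prob": spec.escalation_cycle_prob,
            "escalation_cost_multiplier": spec.escalation_cost_multiplier,
            "convergence_cycles": spec.convergence_cycles,
            "efficacy": asdict(mi.efficacy[t]),
        }
        if spec.weight_based_doses_mg:
            d["weight_based_doses_mg"] = dict(spec.weight_based_doses_mg)
        if t in mi.efficacy_cdai70:
            d["efficacy_cdai70"] = asdict(mi.efficacy_cdai70[t])
        treatments[t] = d

    unpub: dict[str, Any] = {
        "soc_transition_matrix": np.asarray(mi.unpublished.soc_transition_matrix).tolist(),
        "post_surgery_distribution": np.asarray(mi.unpublished.post_surgery_distribution).tolist(),
        "mortality_table": {int(k): float(v) for k, v in mi.unpublished.mortality_table.items()},
        "maintenance_targets": {t: dict(v) for t, v in mi.unpublished.maintenance_targets.items()},
        "surgery_complication_prob": mi.unpublished.surgery_complication_prob,
    }
    if mi.unpublished.biologic_matrices is not None:
        unpub["biologic_matrices"] = {
            t: np.asarray(m).tolist() for t, m in mi.unpublished.biologic_matrices.items()
        }

    return {
        "schema_version": mi.schema_version,
        "population": asdict(mi.population),
        "intervention": mi.intervention,
        "comparator": mi.comparator,
        "treatments": treatments,
        "costs": asdict(mi.costs),
        "utilities": asdict(mi.utilities),
        "settings": asdict(mi.settings),
        "unpublished": unpub,
        "provenance_synthetic": list(mi.provenance_synthetic),
    }


def load_model_inputs(source) -> ModelInputs:
    """Load and validate model inputs from a YAML file path or mapping.

    Raises :class:`SchemaError` for missing fields and
    :class:`InputValidationError` (listing *all* violations) for invariant
    failures.
    """
    if isinstance(source, Mapping):
        return model_inputs_from_dict(source)
    with open(source, "r") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise SchemaError(f"document at {source!r} is not a mapping")
    return model_inputs_from_dict(doc)


def save_model_inputs(mi: ModelInputs, path) -> None:
    """Write model inputs to a YAML document (round-trips exactly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(model_inputs_to_dict(mi), fh, sort_keys=False)


_FIXTURES = {
    "conventional_care_failure": "conventional_care.yaml",
    "tnf_failure": "tnf_failure.yaml",
}


def paper_baseline_inputs(population_name: str) -> ModelInputs:
    """Packaged baseline inputs for one analysis population.

    Published values are shipped verbatim; unpublished ones come from the
    synthetic-data defaults and are listed in ``provenance_synthetic``.
    """
    if population_name not in _FIXTURES:
        raise KeyError(
            f"unknown population {population_name!r}; expected one of {POPULATIONS}"
        )
    ref = importlib.resources.files("cdcea.data") / _FIXTURES[population_name]
    doc = yaml.safe_load(ref.read_text())
    return model_inputs_from_dict(doc)


def clone_inputs(mi: ModelInputs) -> ModelInputs:
    """Deep copy of a ModelInputs bundle."""
    return copy.deepcopy(mi)
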