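"""Induction-phase decision tree.

All patients enter in the moderate-to-severe state and receive the first
induction dose.  At the assessment visit, responders split across the CDAI
states from the remission rate alpha, the response rate beta and the
fraction gamma of responders who stay moderate-to-severe:

    remission            alpha
    mild                 beta - (alpha + beta * gamma)
    moderate-to-severe   beta * gamma
    non-response         1 - beta

First-dose non-responders receive a second induction dose and are assessed
again with the same split applied to the second-dose rates; second-dose
non-responders move to non-biologic standard of care.  A one-off induction
surgery probability is then drawn proportionally from all states.  The tree
also accrues induction-phase costs (drug, administration, health-state,
indirect, adverse events) and QALYs, all at the moderate-to-severe rates
since every patient starts there and within-induction improvement timing is
not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import states as st
from .parameters import InductionEfficacy, ModelInputs, TreatmentSpec

__all__ = [
    "InfeasibleSplitError",
    "InductionDistribution",
    "InductionResult",
    "eq_split",
    "induction_transition_split",
    "run_induction",
]

DAYS_PER_WEEK = 7.0
DAYS_PER_YEAR = 365.25


class InfeasibleSplitError(ValueError):
    """The induction split is infeasible: requires beta >= alpha + beta*gamma."""


@dataclass
class InductionDistribution:
    """Cohort fractions after an induction assessment."""

    remission: float
    mild: float
    moderate_severe: float
    non_response: float
    surgery: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.remission, self.mild, self.moderate_severe,
                         self.non_response, self.surgery])

    @property
    def total(self) -> float:
        return float(self.as_array().sum())


def eq_split(alpha: float, beta: float, gamma: float) -> InductionDistribution:
    """Split one assessment outcome into CDAI states.

    Parameters are the remission rate ``alpha``, response rate ``beta`` and
    the fraction ``gamma`` of responders remaining moderate-to-severe.
    Raises :class:`InfeasibleSplitError` when the implied mild fraction
    ``beta - (alpha + beta*gamma)`` is negative.
    """
    if not (0.0 <= alpha <= beta <= 1.0):
        raise InfeasibleSplitError(
            f"need 0 <= alpha <= beta <= 1, got alpha={alpha}, beta={beta}"
        )
    if not (0.0 <= gamma <= 1.0):
        raise InfeasibleSplitError(f"gamma must be in [0,1], got {gamma}")
    mild = beta - (alpha + beta * gamma)
    if mild < -1e-12:
        raise InfeasibleSplitError(
            "infeasible split: beta - (alpha + beta*gamma) = "
            f"{mild:.6g} < 0 (the mild fraction must be non-negative)"
        )
    return InductionDistribution(
        remission=alpha,
        mild=max(mild, 0.0),
        moderate_severe=beta * gamma,
        non_response=1.0 - beta,
    )


def induction_transition_split(
    efficacy: InductionEfficacy, gamma: float
) -> InductionDistribution:
    """First-dose assessment split for one treatment's efficacy set."""
    return eq_split(efficacy.alpha_remission, efficacy.beta_response, gamma)


@dataclass
class InductionResult:
    """Outcome of the induction tree for one strategy."""

    treatment: str
    start_of_maintenance_distribution: InductionDistribution
    to_soc_fraction: float
    induction_costs: dict[str, float]
    induction_qalys: float
    induction_duration_weeks: float
    #: fraction of the cohort that responded to the first dose (these accrue
    #: only the shorter first-dose induction span)
    first_dose_response: float = 0.0

    @property
    def total_cost(self) -> float:
        return float(sum(self.induction_costs.values()))

    def initial_occupancy(self) -> np.ndarray:
        """Start-of-maintenance occupancy over the expanded state space.

        Responders start on standard-dose biologic; final non-responders
        start moderate-to-severe on standard of care; induction surgery
        occupancy is split between the two tracks in proportion to their
        mass.
        """
        d = self.start_of_maintenance_distribution
        occ = np.zeros(st.N_EXPANDED)
        occ[st.cdai_index(0, 0)] = d.remission
        occ[st.cdai_index(1, 0)] = d.mild
        occ[st.cdai_index(2, 0)] = d.moderate_severe
        occ[st.cdai_index(2, 2)] = d.non_response
        bio_mass = d.remission + d.mild + d.moderate_severe
        total_alive = bio_mass + d.non_response
        if d.surgery > 0 and total_alive > 0:
            occ[st.surgery_index(0)] = d.surgery * bio_mass / total_alive
            occ[st.surgery_index(2)] = d.surgery * d.non_response / total_alive
        return occ


def _dose_cost(event, spec: TreatmentSpec, inputs: ModelInputs) -> float:
    """Drug acquisition cost of one administration occasion (pro-rata/mg)."""
    pack = inputs.costs.drug_packs[spec.name]
    per_mg = pack["price"] / pack["pack_mg"]
    if event.dose_mg == "weight_based":
        if not spec.weight_based_doses_mg:
            raise ValueError(f"{spec.name}: weight-based dose without band doses")
        bands = inputs.population.weight_bands
        mg = sum(bands[b] * spec.weight_based_doses_mg[b] for b in bands)
    else:
        mg = float(event.dose_mg)
    return per_mg * mg


def _admin_cost(event, inputs: ModelInputs) -> float:
    """Administration cost of one occasion (induction is all in-hospital)."""
    return inputs.costs.iv_admin if event.route == "IV" else inputs.costs.sc_inhospital_admin


def run_induction(inputs: ModelInputs, treatment: str) -> InductionResult:
    """Run the induction decision tree for one strategy.

    Returns the start-of-maintenance distribution, the fraction routed to
    standard of care, and the induction-phase cost breakdown and QALYs.
    """
    if treatment not in inputs.treatments:
        raise KeyError(f"unknown treatment {treatment!r}")
    spec = inputs.treatments[treatment]
    eff = inputs.active_efficacy(treatment)
    gamma = inputs.population.gamma_mod_sev_remainder
    settings = inputs.settings

    s1 = eq_split(eff.alpha_remission, eff.beta_response, gamma)
    s2 = eq_split(eff.second_dose_remission, eff.second_dose_response, gamma)
    nr1 = s1.non_response

    remission = s1.remission + nr1 * s2.remission
    mild = s1.mild + nr1 * s2.mild
    mod_sev = s1.moderate_severe + nr1 * s2.moderate_severe
    to_soc = nr1 * s2.non_response

    # one-off induction surgery, drawn proportionally from every state
    p_surg = settings.induction_surgery_prob
    dist = InductionDistribution(
        remission=remission * (1 - p_surg),
        mild=mild * (1 - p_surg),
        moderate_severe=mod_sev * (1 - p_surg),
        non_response=to_soc * (1 - p_surg),
        surgery=p_surg,
    )

    # --- cost and QALY accrual ------------------------------------------
    drug = sum(_dose_cost(e, spec, inputs) for e in spec.first_doses)
    admin = sum(_admin_cost(e, inputs) for e in spec.first_doses)
    drug += nr1 * sum(_dose_cost(e, spec, inputs) for e in spec.second_doses)
    admin += nr1 * sum(_admin_cost(e, inputs) for e in spec.second_doses)

    # person-time: first-dose responders accrue over the (shorter) first-dose
    # induction span, everyone else to the second assessment
    person_weeks = (
        eff.beta_response * spec.first_duration_weeks
        + nr1 * spec.second_assessment_week
    )
    person_cycles = person_weeks / settings.cycle_length_weeks
    person_years = person_weeks * DAYS_PER_WEEK / DAYS_PER_YEAR

    health_state = inputs.costs.state_direct_2wk["moderate_severe"] * person_cycles
    indirect = (
        inputs.costs.state_indirect_2wk["moderate_severe"] * person_cycles
        if settings.include_indirect_costs
        else 0.0
    )

    rates = inputs.utilities.ae_cycle_rates[treatment]
    ae_cost = person_cycles * sum(
        rates.get(ae, 0.0) * c for ae, c in inputs.costs.ae_unit_costs.items()
    )
    ae_qaly_loss = 0.0
    if settings.include_ae_effects:
        cycle_years = settings.cycle_length_weeks * DAYS_PER_WEEK / DAYS_PER_YEAR
        ae_qaly_loss = person_cycles * sum(
            rates.get(ae, 0.0) * abs(d) * cycle_years
            for ae, d in inputs.utilities.ae_disutilities.items()
        )

    u_ms = inputs.active_utilities()["moderate_severe"]
    qalys = u_ms * person_years - ae_qaly_loss

    return InductionResult(
        treatment=treatment,
        start_of_maintenance_distribution=dist,
        to_soc_fraction=to_soc,
        induction_costs={
            "drug": drug,
            "administration": admin,
            "health_state": health_state,
            "indirect": indirect,
            "adverse_event": ae_cost,
        },
        induction_qalys=qalys,
        induction_duration_weeks=spec.second_assessment_week,
        first_dose_response=eff.beta_response,
    )
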