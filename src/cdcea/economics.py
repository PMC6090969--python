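"""Cost and QALY accrual, discounting and incremental analysis.

Costs are accrued from the societal perspective: direct medical costs
(drug acquisition, administration, health-state resource use, adverse
events, surgical complications) plus indirect productivity costs per health
state.  Drug acquisition is pro-rated over the dosing interval (a 12-week
maintenance dose contributes one sixth of its price per two-week cycle);
administration occasions, by contrast, are lumped at the cycles where a dose
is given, because they are per-occasion by definition.  QALYs weight
start-of-cycle occupancy by state utility.  Both streams are discounted at
annual rates with cycle time ``cycle_index * 14 / 365.25`` years measured
from model entry; the induction phase is added at time zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import states as st
from .induction import InductionResult
from .markov import CohortTrace
from .parameters import ModelInputs

__all__ = [
    "discount_factor",
    "StrategyResult",
    "IncrementalResult",
    "accumulate",
    "incremental_analysis",
]

DAYS_PER_YEAR = 365.25
COST_COMPONENTS = (
    "drug",
    "administration",
    "health_state",
    "indirect",
    "adverse_event",
    "surgery_complication",
)


def discount_factor(time_years, annual_rate: float):
    """Discount factor ``(1 + rate) ** (-t)``; accepts scalars or arrays."""
    if annual_rate < 0:
        raise ValueError(f"annual_rate must be >= 0, got {annual_rate}")
    return (1.0 + annual_rate) ** (-np.asarray(time_years, dtype=float))


@dataclass
class StrategyResult:
    """Discounted cost components and QALYs for one strategy."""

    treatment: str
    components: dict[str, float]
    total_qalys: float
    life_years: float
    discount_rate_costs: float
    discount_rate_effects: float
    horizon_years: float

    @property
    def total_cost(self) -> float:
        return float(sum(self.components.values()))

    def settings_key(self) -> tuple:
        return (self.discount_rate_costs, self.discount_rate_effects,
                self.horizon_years)

    def to_series(self) -> pd.Series:
        s = pd.Series(self.components)
        s["total_cost"] = self.total_cost
        s["total_qalys"] = self.total_qalys
        s["life_years"] = self.life_years
        return s


@dataclass
class IncrementalResult:
    """Incremental comparison of intervention vs comparator."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    classification: str  # intervention_dominates | comparator_dominates |
    #                      icer_reported | degenerate
    explanation: str = ""

    @property
    def dominance(self) -> bool:
        return self.classification in (
            "intervention_dominates", "comparator_dominates"
        )


def _per_cycle_weights(trace: CohortTrace, half_cycle: bool) -> np.ndarray:
    """Occupancy rows used for accrual: start-of-cycle, optionally averaged
    with end-of-cycle (half-cycle correction)."""
    occ = trace.occupancy
    if half_cycle:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[:-1]


def accumulate(
    trace: CohortTrace,
    induction: InductionResult,
    inputs: ModelInputs,
) -> StrategyResult:
    """Accrue discounted costs and QALYs over a cohort trace.

    Induction-phase components enter at time zero (undiscounted); each
    maintenance cycle is discounted at its calendar time from model entry.
    """
    settings = inputs.settings
    treatment = trace.treatment
    spec = inputs.treatments[treatment]
    costs = inputs.costs
    cw = settings.cycle_length_weeks
    cycle_years = cw * 7.0 / DAYS_PER_YEAR

    n = trace.n_cycles
    occ = _per_cycle_weights(trace, settings.half_cycle_correction)
    t_years = trace.weeks[:-1] / 2.0 * 14.0 / DAYS_PER_YEAR  # = weeks*7/365.25
    df_cost = discount_factor(t_years, settings.discount_rate_costs)
    df_eff = discount_factor(t_years, settings.discount_rate_effects)

    m_idx = np.arange(n)
    on_treatment = m_idx < trace.switch_cycle

    std_mass = occ[:, 0:3].sum(axis=1)
    esc_mass = occ[:, 3:6].sum(axis=1)
    soc_mass = occ[:, 6:9].sum(axis=1)
    bio_mass = std_mass + esc_mass

    # --- drug acquisition ------------------------------------------------
    interval_cycles = spec.maintenance_interval_weeks / cw
    per_cycle_price = (
        costs.drug_packs[treatment]["price"]
        * spec.maintenance_dose_mg / costs.drug_packs[treatment]["pack_mg"]
        / interval_cycles
    )
    drug_cycle = np.where(
        on_treatment,
        (std_mass + esc_mass * spec.escalation_cost_multiplier) * per_cycle_price,
        0.0,
    )
    # SoC drug: everyone off biologic, plus concomitant SoC on biologic
    soc_recipients = soc_mass + np.where(
        on_treatment, bio_mass * costs.concomitant_soc_fraction, bio_mass
    )
    drug_cycle = drug_cycle + soc_recipients * costs.soc_drug_cost_2wk
    drug = float((drug_cycle * df_cost).sum())

    # --- administration (IV maintenance occasions only; home SC is free) --
    administration = 0.0
    if spec.maintenance_route == "IV":
        ic = int(round(interval_cycles))
        dose_cycles = (m_idx % max(ic, 1) == 0) & on_treatment
        admin_cycle = np.where(
            dose_cycles,
            (std_mass + esc_mass * spec.escalation_cost_multiplier) * costs.iv_admin,
            0.0,
        )
        administration = float((admin_cycle * df_cost).sum())

    # --- health-state and indirect costs ---------------------------------
    direct_vec = np.zeros(st.N_EXPANDED)
    indirect_vec = np.zeros(st.N_EXPANDED)
    for s in range(3):
        for c, cdai in enumerate(st.CDAI_STATES):
            direct_vec[st.cdai_index(c, s)] = costs.state_direct_2wk[cdai]
            indirect_vec[st.cdai_index(c, s)] = costs.state_indirect_2wk[cdai]
        direct_vec[st.surgery_index(s)] = costs.state_direct_2wk["surgery"]
        indirect_vec[st.surgery_index(s)] = costs.state_indirect_2wk["surgery"]
    health_state = float(((occ @ direct_vec) * df_cost).sum())
    indirect = (
        float(((occ @ indirect_vec) * df_cost).sum())
        if settings.include_indirect_costs
        else 0.0
    )

    # --- adverse events (on biologic, on treatment) -----------------------
    rates = inputs.utilities.ae_cycle_rates[treatment]
    ae_cost_rate = sum(
        rates.get(ae, 0.0) * c for ae, c in costs.ae_unit_costs.items()
    )
    ae_bio = np.where(on_treatment, bio_mass, 0.0)
    adverse_event = float((ae_bio * ae_cost_rate * df_cost).sum())
    ae_disutility_rate = (
        sum(rates.get(ae, 0.0) * abs(d)
            for ae, d in inputs.utilities.ae_disutilities.items())
        if settings.include_ae_effects
        else 0.0
    )

    # --- surgical complications -------------------------------------------
    # one-cycle residence: surgery occupancy at each cycle equals that
    # cycle's fresh intake, so occupancy x complication probability counts
    # each surgery once
    surg_mass = occ[:, 9:12].sum(axis=1)
    surgery_complication = float(
        (surg_mass * inputs.unpublished.surgery_complication_prob
         * costs.surgery_complication_cost * df_cost).sum()
    )

    # --- QALYs and life-years ---------------------------------------------
    u = inputs.active_utilities()
    util_vec = np.zeros(st.N_EXPANDED)
    for s in range(3):
        for c, cdai in enumerate(st.CDAI_STATES):
            util_vec[st.cdai_index(c, s)] = u[cdai]
        util_vec[st.surgery_index(s)] = u["surgery"]
    qaly_cycle = (occ @ util_vec) * cycle_years - ae_bio * ae_disutility_rate * cycle_years
    total_qalys = float((qaly_cycle * df_eff).sum()) + induction.induction_qalys
    alive_mass = occ[:, :st.DEATH].sum(axis=1)
    # maintenance-phase discounted life years (no mortality is modelled
    # within the short induction phase)
    life_years = float((alive_mass * cycle_years * df_eff).sum())

    components = {
        "drug": drug + induction.induction_costs["drug"],
        "administration": administration + induction.induction_costs["administration"],
        "health_state": health_state + induction.induction_costs["health_state"],
        "indirect": indirect + induction.induction_costs["indirect"],
        "adverse_event": adverse_event + induction.induction_costs["adverse_event"],
        "surgery_complication": surgery_complication,
    }
    return StrategyResult(
        treatment=treatment,
        components=components,
        total_qalys=total_qalys,
        life_years=life_years,
        discount_rate_costs=settings.discount_rate_costs,
        discount_rate_effects=settings.discount_rate_effects,
        horizon_years=settings.horizon_years,
    )


def incremental_analysis(
    intervention: StrategyResult, comparator: StrategyResult
) -> IncrementalResult:
    """Incremental cost, incremental QALYs, and ICER or dominance.

    Raises ``ValueError`` when the two arms were run under different
    discount settings or horizons (results would not be comparable).
    """
    if intervention.settings_key() != comparator.settings_key():
        raise ValueError(
            "strategies were run under different discount/horizon settings: "
            f"{intervention.settings_key()} vs {comparator.settings_key()}"
        )
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.total_qalys - comparator.total_qalys

    if abs(dq) < 1e-12 and abs(dc) < 1e-9:
        return IncrementalResult(dc, dq, None, "degenerate",
                                 "arms are economically identical")
    if dc <= 0 and dq >= 0:
        return IncrementalResult(dc, dq, None, "intervention_dominates",
                                 "intervention is cheaper and at least as effective")
    if dc >= 0 and dq <= 0:
        return IncrementalResult(dc, dq, None, "comparator_dominates",
                                 "comparator is cheaper and at least as effective")
    if abs(dq) < 1e-12:
        return IncrementalResult(dc, dq, None, "degenerate",
                                 "QALY difference below resolution; ICER undefined")
    return IncrementalResult(dc, dq, dc / dq, "icer_reported")
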