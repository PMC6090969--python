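"""Maintenance-phase Markov cohort engine.

Simulates the cohort from the end of induction to the model horizon in
two-week cycles over the expanded state space (CDAI state x treatment
status, surgery per status of origin, death).  Within each cycle events
apply in a fixed order:

1. background mortality, by current cohort age, from every alive state;
2. surgery-state exit after a one-cycle stay, to the post-surgery CDAI
   distribution within the originating treatment track;
3. surgery intake from the CDAI states at the per-cycle surgery probability;
4. discontinuation to standard of care (SoC), from the moderate-to-severe
   state on biologic only, at the status-specific probability (on treatment);
5. dose escalation from standard-dose to escalated-dose biologic (when
   enabled, on treatment);
6. CDAI transition by the status-appropriate matrix.

After the treatment duration, drug exposure ends and the biologic tracks'
matrix blends linearly into the SoC matrix over the treatment-specific
convergence period (gradual post-treatment efficacy decline).  Mass
conservation is asserted every cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import states as st
from .induction import InductionResult
from .parameters import ModelInputs

__all__ = [
    "annual_to_cycle_probability",
    "cycle_to_annual_probability",
    "CohortTrace",
    "run_maintenance",
]

_MASS_TOL = 1e-9


def annual_to_cycle_probability(p_annual: float, cycle_weeks: float) -> float:
    """Convert an annual event probability to a per-cycle probability.

    Constant-hazard conversion ``1 - (1 - p)**(cycle_weeks / 52)``.
    """
    if not (0.0 <= p_annual <= 1.0):
        raise ValueError(f"probability must be in [0,1], got {p_annual}")
    return 1.0 - (1.0 - p_annual) ** (cycle_weeks / 52.0)


def cycle_to_annual_probability(p_cycle: float, cycle_weeks: float) -> float:
    """Inverse of :func:`annual_to_cycle_probability`."""
    if not (0.0 <= p_cycle <= 1.0):
        raise ValueError(f"probability must be in [0,1], got {p_cycle}")
    return 1.0 - (1.0 - p_cycle) ** (52.0 / cycle_weeks)


@dataclass
class CohortTrace:
    """Per-cycle occupancy over the expanded state space.

    Row 0 is the start of maintenance; row ``m`` is the occupancy after
    ``m`` cycles.  ``weeks`` are measured from model entry (induction start),
    so discounting and the treatment-duration switch share one clock.
    """

    treatment: str
    occupancy: np.ndarray        # (n_cycles + 1, N_EXPANDED)
    weeks: np.ndarray            # (n_cycles + 1,)
    ages: np.ndarray             # (n_cycles + 1,)
    switch_cycle: int            # first maintenance cycle off treatment
    offset_weeks: float          # induction duration preceding row 0

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def death(self) -> np.ndarray:
        return self.occupancy[:, st.DEATH]

    def status_mass(self, statuses: tuple[int, ...]) -> np.ndarray:
        """Total CDAI-state occupancy over the given treatment statuses."""
        cols = [st.cdai_index(c, s) for s in statuses for c in range(3)]
        return self.occupancy[:, cols].sum(axis=1)

    def surgery_mass(self) -> np.ndarray:
        return self.occupancy[:, [st.surgery_index(s) for s in range(3)]].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=st.expanded_labels())
        df.insert(0, "week", self.weeks)
        df.insert(1, "age", self.ages)
        return df


def run_maintenance(
    induction_result: InductionResult,
    inputs: ModelInputs,
    matrices: dict[str, np.ndarray],
    n_cycles: int | None = None,
) -> CohortTrace:
    """Run the maintenance cohort simulation for one strategy.

    ``matrices`` must provide ``"biologic"`` (standard dose) and may provide
    ``"escalated"`` (defaults to the standard-dose matrix: escalation is
    modelled as restoring efficacy at a higher drug cost).  The SoC matrix
    comes from the unpublished inputs.
    """
    settings = inputs.settings
    treatment = induction_result.treatment
    spec = inputs.treatments[treatment]
    pop = inputs.population

    bio = np.asarray(matrices["biologic"], dtype=float)
    esc = np.asarray(matrices.get("escalated", bio), dtype=float)
    soc = np.asarray(inputs.unpublished.soc_transition_matrix, dtype=float)
    for name, m in (("biologic", bio), ("escalated", esc), ("soc", soc)):
        if m.shape != (3, 3):
            raise ValueError(f"{name} matrix: expected 3x3, got {m.shape}")
    post = np.asarray(inputs.unpublished.post_surgery_distribution, dtype=float)

    offset_weeks = induction_result.induction_duration_weeks
    cw = settings.cycle_length_weeks
    total_cycles = settings.horizon_cycles - int(round(offset_weeks / cw))
    if n_cycles is None:
        n_cycles = total_cycles
    if n_cycles < 0:
        raise ValueError("horizon shorter than the induction phase")

    switch_cycle = max(
        0, int(round((settings.treatment_duration_weeks - offset_weeks) / cw))
    )
    p_surg = annual_to_cycle_probability(settings.annual_surgery_prob, cw)
    p_disc = (spec.discontinuation_cycle_prob_standard,
              spec.discontinuation_cycle_prob_escalated)
    p_esc = spec.escalation_cycle_prob if settings.allow_dose_escalation else 0.0

    mort = inputs.unpublished.mortality_table
    ages = pop.mean_age + (offset_weeks + cw * np.arange(n_cycles + 1)) * 7.0 / 365.25
    age_idx = np.floor(ages).astype(int)
    missing = [int(a) for a in np.unique(age_idx[:-1]) if a not in mort]
    if missing:
        raise ValueError(
            f"mortality table exhausted before horizon (missing ages {missing[:3]}...)"
        )
    q_cycle = np.array([mort[int(a)] for a in age_idx[:-1]])

    occ = np.zeros((n_cycles + 1, st.N_EXPANDED))
    occ[0] = induction_result.initial_occupancy()
    surg_cols = [st.surgery_index(s) for s in range(3)]

    v = occ[0].copy()
    for m in range(n_cycles):
        on_treatment = m < switch_cycle
        q = q_cycle[m]

        # 1. mortality from every alive state
        alive = v[:st.DEATH].sum()
        v[st.DEATH] += alive * q
        v[:st.DEATH] *= 1.0 - q

        # 2. surgery exit (one-cycle residence) back into the same track
        for s in range(3):
            mass = v[surg_cols[s]]
            if mass > 0:
                v[surg_cols[s]] = 0.0
                v[s * 3:s * 3 + 3] += mass * post

        # 3. surgery intake from the CDAI states
        if p_surg > 0:
            for s in range(3):
                take = v[s * 3:s * 3 + 3] * p_surg
                v[s * 3:s * 3 + 3] -= take
                v[surg_cols[s]] += take.sum()

        # 4. discontinuation: moderate-to-severe on biologic -> SoC
        if on_treatment:
            for s in (0, 1):
                take = v[st.cdai_index(2, s)] * p_disc[s]
                v[st.cdai_index(2, s)] -= take
                v[st.cdai_index(2, 2)] += take

        # 5. dose escalation: standard -> escalated across CDAI states
        if on_treatment and p_esc > 0:
            take = v[0:3] * p_esc
            v[0:3] -= take
            v[3:6] += take

        # 6. CDAI transition by the status-appropriate matrices
        if on_treatment:
            m_std, m_esc = bio, esc
        else:
            k = m - switch_cycle + 1
            prog = 1.0 if spec.convergence_cycles == 0 else min(
                1.0, k / spec.convergence_cycles
            )
            m_std = (1.0 - prog) * bio + prog * soc
            m_esc = (1.0 - prog) * esc + prog * soc
        v[0:3] = v[0:3] @ m_std
        v[3:6] = v[3:6] @ m_esc
        v[6:9] = v[6:9] @ soc

        total = v.sum()
        if abs(total - 1.0) > _MASS_TOL:
            raise AssertionError(
                f"mass conservation violated at cycle {m}: sum={total!r}"
            )
        v /= total  # remove accumulated rounding, stays within tolerance
        occ[m + 1] = v

    return CohortTrace(
        treatment=treatment,
        occupancy=occ,
        weeks=offset_weeks + cw * np.arange(n_cycles + 1),
        ages=ages,
        switch_cycle=switch_cycle,
        offset_weeks=offset_weeks,
    )
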