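"""Health-state space of the model.

Five clinical health states: three Crohn's Disease Activity Index (CDAI)
severity bands (remission CDAI < 150, mild 150 <= CDAI < 220, moderate-severe
220 <= CDAI < 600), a transient surgery state and an absorbing death state.

The maintenance-phase cohort engine expands the CDAI states by treatment
status (standard-dose biologic, escalated-dose biologic, standard of care),
because discontinuation and dose-escalation probabilities are status
specific.  Surgery occupancy is also tracked per status so that patients
return from surgery to the treatment track they came from.
"""

from __future__ import annotations

CDAI_STATES: tuple[str, ...] = ("remission", "mild", "moderate_severe")
HEALTH_STATES: tuple[str, ...] = CDAI_STATES + ("surgery", "death")

#: Treatment-status tracks in the maintenance phase.
STATUSES: tuple[str, ...] = ("biologic_standard", "biologic_escalated", "soc")

N_CDAI = len(CDAI_STATES)
N_STATUS = len(STATUSES)

#: Expanded-state layout: 9 CDAI x status cells, 3 surgery cells (one per
#: status of origin), then death.  13 states in total.
N_EXPANDED = N_CDAI * N_STATUS + N_STATUS + 1
DEATH = N_EXPANDED - 1


def cdai_index(cdai: int, status: int) -> int:
    """Flat index of a (CDAI state, treatment status) cell."""
    return status * N_CDAI + cdai


def surgery_index(status: int) -> int:
    """Flat index of the surgery cell for a given status of origin."""
    return N_CDAI * N_STATUS + status


def expanded_labels() -> list[str]:
    """Column labels for the expanded occupancy vector."""
    labels = [
        f"{CDAI_STATES[c]}|{STATUSES[s]}"
        for s in range(N_STATUS)
        for c in range(N_CDAI)
    ]
    labels += [f"surgery|{STATUSES[s]}" for s in range(N_STATUS)]
    labels.append("death")
    return labels
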