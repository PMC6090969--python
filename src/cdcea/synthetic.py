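"""Synthetic stand-ins for unpublished inputs, random scenarios, and an
individual-level microsimulation oracle.

Several inputs the model needs were never published: the standard-of-care
(SoC) CDAI transition matrix, the post-surgery state distribution, background
mortality, the per-treatment end-of-maintenance target distributions from the
network meta-analysis / treatment-sequence analysis, and the surgical
complication probability.  This module generates documented, seeded stand-ins
for all of them (``[synthetic]`` provenance), full random-but-valid model
input bundles for property testing, and a patient-level microsimulation that
serves as an independent oracle for the cohort engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import states as st
from .parameters import ModelInputs, UnpublishedInputs

__all__ = [
    "SyntheticSpec",
    "default_unpublished_inputs",
    "generate_unpublished_inputs",
    "generate_random_scenario",
    "microsimulate",
    "MicrosimResult",
]

# Default synthetic SoC matrix: biased toward worse states (per-cycle
# remission->mild 0.05, mild->moderate-severe 0.08, moderate-severe->mild
# 0.03), with small improvement probabilities so the chain is not absorbing.
SOC_MATRIX_DEFAULT = np.array(
    [
        [0.95, 0.05, 0.00],
        [0.02, 0.90, 0.08],
        [0.01, 0.03, 0.96],
    ]
)

POST_SURGERY_DEFAULT = np.array([0.50, 0.30, 0.20])

#: Gompertz hazard parameters for the synthetic all-cause mortality table:
#: annual death probability a*exp(b*age), roughly the adult mortality shape
#: (doubling time ~8 years).  Not an official national life table.
GOMPERTZ_A = 3.0e-5
GOMPERTZ_B = 0.085
MORTALITY_AGES = (30, 110)

#: Default end-of-maintenance target distributions {remission, mild} per
#: treatment and population; the intervention's remission target exceeds the
#: comparator's, matching the qualitative ordering the efficacy evidence
#: implies.
MAINTENANCE_TARGETS_DEFAULT = {
    "conventional_care_failure": {
        "ustekinumab": {"remission": 0.42, "mild": 0.27},
        "adalimumab": {"remission": 0.38, "mild": 0.27},
    },
    "tnf_failure": {
        "ustekinumab": {"remission": 0.33, "mild": 0.26},
        "vedolizumab": {"remission": 0.28, "mild": 0.25},
    },
}

SURGERY_COMPLICATION_RANGE = (0.05, 0.30)
SURGERY_COMPLICATION_DEFAULT = 0.15


def gompertz_cycle_mortality(
    cycle_weeks: float = 2.0,
    a: float = GOMPERTZ_A,
    b: float = GOMPERTZ_B,
    ages: tuple[int, int] = MORTALITY_AGES,
) -> dict[int, float]:
    """Per-cycle death probability by integer age, Gompertz-shaped."""
    table = {}
    for age in range(ages[0], ages[1] + 1):
        q_annual = min(1.0, a * np.exp(b * age))
        table[age] = 1.0 - (1.0 - q_annual) ** (cycle_weeks / 52.0)
    return table


@dataclass
class SyntheticSpec:
    """Controls the synthetic generator; equal specs give equal outputs."""

    seed: int = 0
    population_name: str = "conventional_care_failure"
    treatments: tuple[str, ...] = ("ustekinumab", "adalimumab")
    #: relative jitter applied around the defaults; 0 = the defaults exactly.
    jitter: float = 0.0
    complication_range: tuple[float, float] = SURGERY_COMPLICATION_RANGE
    microsim_patients: int = 100_000


def default_unpublished_inputs(
    population_name: str, treatments: tuple[str, ...]
) -> UnpublishedInputs:
    """Deterministic default stand-ins for the unpublished inputs."""
    return generate_unpublished_inputs(
        SyntheticSpec(population_name=population_name, treatments=tuple(treatments))
    )


def _jitter_simplex(row: np.ndarray, rng: np.random.Generator, scale: float) -> np.ndarray:
    if scale <= 0:
        return row.copy()
    out = np.clip(row * np.exp(rng.normal(0.0, scale, row.shape)), 1e-9, None)
    out[row == 0] = 0.0
    s = out.sum()
    return out / s if s > 0 else row.copy()


def generate_unpublished_inputs(spec: SyntheticSpec) -> UnpublishedInputs:
    """Generate the full unpublished-input bundle for one population.

    With ``jitter == 0`` the documented defaults are returned verbatim;
    larger jitter perturbs them reproducibly (seeded) while preserving every
    type invariant and the intervention >= comparator remission-target
    ordering.
    """
    rng = np.random.default_rng(spec.seed)
    soc = np.vstack(
        [_jitter_simplex(r, rng, spec.jitter) for r in SOC_MATRIX_DEFAULT]
    )
    post = _jitter_simplex(POST_SURGERY_DEFAULT, rng, spec.jitter)

    base_targets = MAINTENANCE_TARGETS_DEFAULT.get(spec.population_name)
    targets: dict[str, dict[str, float]] = {}
    prev_remission = None
    for t in spec.treatments:
        if base_targets and t in base_targets:
            tr, tm = base_targets[t]["remission"], base_targets[t]["mild"]
        else:
            tr, tm = 0.35, 0.25
        if spec.jitter > 0:
            tr = float(np.clip(tr * np.exp(rng.normal(0, spec.jitter)), 0.01, 0.9))
            tm = float(np.clip(tm * np.exp(rng.normal(0, spec.jitter)), 0.01, 0.9))
            if tr + tm > 0.95:
                s = 0.95 / (tr + tm)
                tr, tm = tr * s, tm * s
        # keep the intervention-first ordering: later treatments never beat
        # the first one on the remission target
        if prev_remission is not None and tr > prev_remission:
            tr = prev_remission
        prev_remission = tr if prev_remission is None else prev_remission
        targets[t] = {"remission": float(tr), "mild": float(tm)}

    lo, hi = spec.complication_range
    if spec.jitter > 0:
        compl = float(rng.uniform(lo, hi))
    else:
        compl = SURGERY_COMPLICATION_DEFAULT
    return UnpublishedInputs(
        soc_transition_matrix=soc,
        post_surgery_distribution=post,
        mortality_table=gompertz_cycle_mortality(),
        maintenance_targets=targets,
        surgery_complication_prob=compl,
    )


# ---------------------------------------------------------------------------
# Random full scenarios for property tests
# ---------------------------------------------------------------------------


def generate_random_scenario(seed: int, horizon_years: float | None = None) -> ModelInputs:
    """A fully valid random ModelInputs bundle (small horizon by default).

    Built by randomising every substantive numeric input of the packaged
    baseline document; intended for property-based testing of the whole
    pipeline, not for realistic projections.
    """
    from .parameters import paper_baseline_inputs, clone_inputs

    rng = np.random.default_rng(seed)
    mi = clone_inputs(paper_baseline_inputs("conventional_care_failure"))

    for t in mi.strategies:
        beta = float(rng.uniform(0.2, 0.8))
        alpha = float(rng.uniform(0.0, beta * (1.0 - 0.2)))
        beta2 = float(rng.uniform(0.1, 0.7))
        alpha2 = float(rng.uniform(0.0, beta2 * (1.0 - 0.2)))
        eff = mi.efficacy[t]
        eff.beta_response, eff.alpha_remission = beta, alpha
        eff.second_dose_response, eff.second_dose_remission = beta2, alpha2
        spec = mi.treatments[t]
        spec.discontinuation_cycle_prob_standard = float(rng.uniform(0.0, 0.3))
        spec.discontinuation_cycle_prob_escalated = float(rng.uniform(0.0, 0.3))
        spec.escalation_cycle_prob = float(rng.uniform(0.0, 0.05))
        spec.convergence_cycles = int(rng.integers(0, 30))
    # gamma small enough to keep every Eq.-1 split feasible
    mi.population.gamma_mod_sev_remainder = float(rng.uniform(0.0, 0.15))
    mi.population.mean_age = float(rng.uniform(30.0, 55.0))

    for d in (mi.costs.state_direct_2wk, mi.costs.state_indirect_2wk,
              mi.costs.ae_unit_costs):
        for k in d:
            d[k] = float(d[k] * rng.uniform(0.5, 1.5))
    mi.costs.surgery_complication_cost *= float(rng.uniform(0.5, 1.5))
    mi.costs.soc_drug_cost_2wk *= float(rng.uniform(0.5, 1.5))

    u_ms = float(rng.uniform(0.3, 0.6))
    u_mild = float(rng.uniform(u_ms, 0.85))
    u_rem = float(rng.uniform(u_mild, 0.95))
    mi.utilities.state_utilities = {
        "remission": u_rem, "mild": u_mild,
        "moderate_severe": u_ms, "surgery": u_ms,
    }

    s = mi.settings
    s.horizon_years = float(horizon_years if horizon_years is not None
                            else rng.uniform(3.0, 8.0))
    s.treatment_duration_years = float(rng.uniform(1.0, min(2.0, s.horizon_years)))
    s.discount_rate_costs = float(rng.uniform(0.0, 0.05))
    s.discount_rate_effects = float(rng.uniform(0.0, 0.05))
    s.induction_surgery_prob = float(rng.uniform(0.0, 0.05))
    s.annual_surgery_prob = float(rng.uniform(0.0, 0.15))
    s.allow_dose_escalation = bool(rng.random() < 0.7)

    up = mi.unpublished
    up.soc_transition_matrix = rng.dirichlet(np.full(3, 5.0), size=3)
    up.post_surgery_distribution = rng.dirichlet(np.full(3, 5.0))
    for t in mi.strategies:
        tr = float(rng.uniform(0.05, 0.6))
        tm = float(rng.uniform(0.05, min(0.9 - tr, 0.5)))
        up.maintenance_targets[t] = {"remission": tr, "mild": tm}
    up.surgery_complication_prob = float(rng.uniform(0.0, 0.3))

    return mi.check()


# ---------------------------------------------------------------------------
# Individual-level microsimulation oracle
# ---------------------------------------------------------------------------


@dataclass
class MicrosimResult:
    """Mean occupancy trajectory and Monte-Carlo standard errors."""

    mean_occupancy: np.ndarray  # (n_cycles + 1, N_EXPANDED)
    standard_error: np.ndarray  # same shape, sqrt(p(1-p)/n)
    n_patients: int
    seed: int


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray, n: int) -> np.ndarray:
    """Draw n categorical indices from one probability vector."""
    return np.searchsorted(np.cumsum(probs), rng.random(n), side="right").clip(
        0, len(probs) - 1
    )


def microsimulate(
    induction_result,
    inputs: ModelInputs,
    matrices: dict[str, np.ndarray],
    treatment: str,
    n_patients: int,
    seed: int,
    n_cycles: int | None = None,
) -> MicrosimResult:
    """Patient-level simulation of the maintenance phase.

    Applies the same per-cycle event order as the cohort engine (mortality,
    surgery exit, surgery intake, discontinuation, escalation, CDAI
    transition) to individually simulated patients via categorical draws.
    Implemented independently of :mod:`cdcea.markov`: no transition code is
    shared, so agreement between the two is a genuine cross-check.
    """
    rng = np.random.default_rng(seed)
    settings = inputs.settings
    spec = inputs.treatments[treatment]
    pop = inputs.population

    offset_weeks = induction_result.induction_duration_weeks
    total_cycles = settings.horizon_cycles - int(round(offset_weeks / settings.cycle_length_weeks))
    if n_cycles is None:
        n_cycles = total_cycles
    n_cycles = min(n_cycles, total_cycles)

    switch_cycle = max(
        0,
        int(round((settings.treatment_duration_weeks - offset_weeks)
                  / settings.cycle_length_weeks)),
    )
    p_surg = 1.0 - (1.0 - settings.annual_surgery_prob) ** (
        settings.cycle_length_weeks / 52.0
    )
    p_disc = {
        0: spec.discontinuation_cycle_prob_standard,
        1: spec.discontinuation_cycle_prob_escalated,
    }
    p_esc = spec.escalation_cycle_prob if settings.allow_dose_escalation else 0.0
    post = np.asarray(inputs.unpublished.post_surgery_distribution, dtype=float)
    soc = np.asarray(inputs.unpublished.soc_transition_matrix, dtype=float)
    bio = np.asarray(matrices["biologic"], dtype=float)
    esc_m = np.asarray(matrices.get("escalated", matrices["biologic"]), dtype=float)
    mort = inputs.unpublished.mortality_table

    start = induction_result.initial_occupancy()
    state = _sample_categorical(rng, start, n_patients).astype(np.int64)

    occ = np.zeros((n_cycles + 1, st.N_EXPANDED))
    occ[0] = np.bincount(state, minlength=st.N_EXPANDED) / n_patients

    for m in range(n_cycles):
        age = int(np.floor(
            pop.mean_age + (offset_weeks + m * settings.cycle_length_weeks) * 7.0 / 365.25
        ))
        q = mort[age]
        on_treatment = m < switch_cycle

        # 1. background mortality from every alive state
        alive = state != st.DEATH
        dies = alive & (rng.random(n_patients) < q)
        state[dies] = st.DEATH

        # 2. surgery exit after a one-cycle stay: back to the CDAI states of
        #    the originating treatment track
        in_surg = (state >= 9) & (state < 12)
        if in_surg.any():
            status = state[in_surg] - 9
            new_cdai = _sample_categorical(rng, post, int(in_surg.sum()))
            state[in_surg] = status * 3 + new_cdai

        # 3. surgery intake from the CDAI states
        in_cdai = state < 9
        goes = in_cdai & (rng.random(n_patients) < p_surg)
        if goes.any():
            state[goes] = 9 + state[goes] // 3

        # 4. discontinuation: moderate-severe on biologic only, on treatment
        if on_treatment:
            for status in (0, 1):
                mask = state == status * 3 + 2
                d = mask & (rng.random(n_patients) < p_disc[status])
                state[d] = 2 * 3 + 2  # moderate-severe on SoC

        # 5. dose escalation: standard-dose biologic -> escalated
        if on_treatment and p_esc > 0:
            mask = state < 3
            e = mask & (rng.random(n_patients) < p_esc)
            state[e] += 3

        # 6. CDAI transition by the status-appropriate matrix
        if on_treatment:
            m_std, m_esc = bio, esc_m
        else:
            k = m - switch_cycle + 1
            prog = 1.0 if spec.convergence_cycles == 0 else min(
                1.0, k / spec.convergence_cycles
            )
            m_std = (1.0 - prog) * bio + prog * soc
            m_esc = (1.0 - prog) * esc_m + prog * soc
        pre_transition = state.copy()
        for status, mat in ((0, m_std), (1, m_esc), (2, soc)):
            for c in range(3):
                mask = pre_transition == status * 3 + c
                if mask.any():
                    new_c = _sample_categorical(rng, mat[c], int(mask.sum()))
                    state[mask] = status * 3 + new_c

        occ[m + 1] = np.bincount(state, minlength=st.N_EXPANDED) / n_patients

    se = np.sqrt(occ * (1.0 - occ) / n_patients)
    return MicrosimResult(mean_occupancy=occ, standard_error=se,
                          n_patients=n_patients, seed=seed)
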