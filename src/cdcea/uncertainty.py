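"""Scenario analyses and probabilistic sensitivity analysis.

The scenario engine re-runs the full pipeline under parameter overrides
addressed by dotted paths into the input bundle (for example
``settings.discount_rate_costs`` or ``costs.state_direct_2wk.moderate_severe``);
the default grid covers the usual one-way and structural variations:
discounting 0%/5% (costs, effects, both), shorter horizons, longer treatment
duration, excluding indirect costs, no dose escalation, doubled
moderate-to-severe resource cost, the CDAI-70 response criterion, no
adverse-event utility effect, and alternative utility sets.

The PSA draws parameters from standard health-economic families -
probabilities and utilities from beta (method of moments), costs from gamma,
efficacy odds from lognormal, transition-matrix rows from Dirichlet - with a
default uncertainty scale of 10% of the mean, and summarises the iterations
as cost-effectiveness acceptability curves (CEACs) via net monetary benefit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .parameters import ModelInputs, clone_inputs
from .pipeline import ComparisonResult, calibrate_strategy_matrix, run_comparison
from .induction import run_induction

__all__ = [
    "Scenario",
    "apply_overrides",
    "default_scenario_grid",
    "run_owsa",
    "nmb",
    "PSADistributionSpec",
    "PSAResults",
    "draw_psa_inputs",
    "run_psa",
    "ceac",
]


# ---------------------------------------------------------------------------
# Scenario engine
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """A named set of parameter overrides (dotted path -> value)."""

    name: str
    overrides: dict[str, Any] = field(default_factory=dict)


def _set_path(obj: Any, path: str, value: Any) -> None:
    parts = path.split(".")
    cur = obj
    for p in parts[:-1]:
        if isinstance(cur, dict):
            if p not in cur:
                raise KeyError(f"unknown override path: {path!r} (at {p!r})")
            cur = cur[p]
        elif dataclasses.is_dataclass(cur) and hasattr(cur, p):
            cur = getattr(cur, p)
        else:
            raise KeyError(f"unknown override path: {path!r} (at {p!r})")
    leaf = parts[-1]
    if isinstance(cur, dict):
        if leaf not in cur:
            raise KeyError(f"unknown override path: {path!r} (at {leaf!r})")
        cur[leaf] = value
    elif dataclasses.is_dataclass(cur) and hasattr(cur, leaf):
        setattr(cur, leaf, value)
    else:
        raise KeyError(f"unknown override path: {path!r} (at {leaf!r})")


def apply_overrides(base: ModelInputs, overrides: dict[str, Any]) -> ModelInputs:
    """Return a validated copy of ``base`` with the overrides applied.

    ``base`` itself is never mutated, so applying and discarding a scenario
    trivially restores the original inputs.
    """
    mi = clone_inputs(base)
    for path, value in overrides.items():
        _set_path(mi, path, value)
    return mi.check()


def default_scenario_grid(base: ModelInputs) -> list[Scenario]:
    """The packaged one-way / structural scenario grid."""
    ms_cost = base.costs.state_direct_2wk["moderate_severe"]
    grid = [
        Scenario("base_case", {}),
        Scenario("discount_costs_0", {"settings.discount_rate_costs": 0.0}),
        Scenario("discount_costs_5", {"settings.discount_rate_costs": 0.05}),
        Scenario("discount_effects_0", {"settings.discount_rate_effects": 0.0}),
        Scenario("discount_effects_5", {"settings.discount_rate_effects": 0.05}),
        Scenario("discount_both_0", {"settings.discount_rate_costs": 0.0,
                                     "settings.discount_rate_effects": 0.0}),
        Scenario("discount_both_5", {"settings.discount_rate_costs": 0.05,
                                     "settings.discount_rate_effects": 0.05}),
        Scenario("horizon_15y", {"settings.horizon_years": 15.0}),
        Scenario("horizon_5y", {"settings.horizon_years": 5.0}),
        Scenario("treatment_duration_5y",
                 {"settings.treatment_duration_years": 5.0}),
        Scenario("no_indirect_costs", {"settings.include_indirect_costs": False}),
        Scenario("no_dose_escalation", {"settings.allow_dose_escalation": False}),
        Scenario("mod_severe_resource_cost_doubled",
                 {"costs.state_direct_2wk.moderate_severe": 2 * ms_cost}),
        Scenario("response_criterion_cdai70",
                 {"settings.response_criterion": "CDAI70"}),
        Scenario("no_ae_effect", {"settings.include_ae_effects": False}),
    ]
    for name in base.utilities.alternative_sets:
        grid.append(Scenario(f"utilities_{name}", {"settings.utility_set": name}))
    return grid


def run_owsa(
    base: ModelInputs,
    scenarios: list[Scenario] | None = None,
    calibration_seed: int = 0,
) -> pd.DataFrame:
    """Run the full pipeline per scenario; one result row per scenario."""
    if scenarios is None:
        scenarios = default_scenario_grid(base)
    rows = []
    for sc in scenarios:
        mi = apply_overrides(base, sc.overrides)
        res = run_comparison(mi, calibration_seed=calibration_seed)
        inc = res.incremental
        rows.append({
            "scenario": sc.name,
            "cost_intervention": res.intervention.result.total_cost,
            "cost_comparator": res.comparator.result.total_cost,
            "qalys_intervention": res.intervention.result.total_qalys,
            "qalys_comparator": res.comparator.result.total_qalys,
            "delta_cost": inc.delta_cost,
            "delta_qalys": inc.delta_qalys,
            "icer": inc.icer if inc.icer is not None else np.nan,
            "classification": inc.classification,
        })
    return pd.DataFrame(rows).set_index("scenario")


# ---------------------------------------------------------------------------
# Net monetary benefit and CEAC
# ---------------------------------------------------------------------------


def nmb(delta_cost: float, delta_qalys: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * dQALY - dCost`` at a willingness to pay."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return wtp * delta_qalys - delta_cost


DEFAULT_WTP_GRID = np.arange(0.0, 200_001.0, 1000.0)


@dataclass
class PSAResults:
    """Per-iteration incremental outcomes of a PSA run."""

    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    seed: int
    n_iterations: int

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(self.n_iterations),
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
        })


def ceac(psa: PSAResults, wtp_grid=None) -> pd.DataFrame:
    """Probability the intervention is cost-effective across WTP values.

    For each willingness-to-pay the fraction of iterations with strictly
    positive net monetary benefit (an NMB of exactly zero counts as not
    cost-effective).
    """
    if psa.n_iterations == 0:
        raise ValueError("empty PSA results")
    grid = np.asarray(DEFAULT_WTP_GRID if wtp_grid is None else wtp_grid,
                      dtype=float)
    if grid.size == 0:
        raise ValueError("empty WTP grid")
    nmb_matrix = grid[:, None] * psa.delta_qalys[None, :] - psa.delta_cost[None, :]
    prob = (nmb_matrix > 0).mean(axis=1)
    return pd.DataFrame({"wtp": grid, "probability_cost_effective": prob})


# ---------------------------------------------------------------------------
# PSA input drawing
# ---------------------------------------------------------------------------


@dataclass
class PSADistributionSpec:
    """Distribution families and uncertainty scales for the PSA.

    ``relative_se`` is the default standard error as a fraction of the mean;
    ``matrix_ess`` is the Dirichlet effective sample size for transition
    matrix rows (larger = tighter around the calibrated matrix).  A
    ``relative_se`` of 0 with infinite ESS reproduces the base inputs.
    """

    relative_se: float = 0.10
    matrix_ess: float = 200.0
    sample_utilities: bool = True
    sample_costs: bool = True
    sample_efficacy: bool = True
    sample_event_probs: bool = True
    sample_matrices: bool = True
    max_retries: int = 100


def _beta_mom(rng, mean: float, se: float) -> float:
    """Beta draw by method of moments; degenerate cases return the mean."""
    if se <= 0 or mean <= 0 or mean >= 1:
        return mean
    se = min(se, 0.5 * np.sqrt(mean * (1 - mean)))
    var = se * se
    nu = mean * (1 - mean) / var - 1.0
    if nu <= 0:
        return mean
    return float(rng.beta(mean * nu, (1 - mean) * nu))


def _gamma_mom(rng, mean: float, se: float) -> float:
    """Gamma draw by method of moments; zero mean or SE returns the mean."""
    if se <= 0 or mean <= 0:
        return mean
    shape = (mean / se) ** 2
    return float(rng.gamma(shape, mean / shape))


def _lognormal_odds(rng, p: float, sigma: float) -> float:
    """Probability re-drawn via lognormal multiplicative noise on its odds."""
    if sigma <= 0 or p <= 0 or p >= 1:
        return p
    odds = p / (1 - p) * float(rng.lognormal(0.0, sigma))
    return odds / (1 + odds)


def _dirichlet_row(rng, row: np.ndarray, ess: float) -> np.ndarray:
    """Dirichlet perturbation of one matrix row; structural zeros stay zero."""
    if not np.isfinite(ess) or ess <= 0:
        return row.copy()
    mask = row > 1e-12
    if mask.sum() <= 1:
        return row.copy()
    out = np.zeros_like(row)
    out[mask] = rng.dirichlet(row[mask] * ess)
    return out * row.sum()


def draw_psa_inputs(
    base: ModelInputs,
    spec: PSADistributionSpec,
    rng: np.random.Generator,
) -> ModelInputs:
    """One PSA parameter draw as a fully valid ModelInputs bundle.

    The biologic transition matrices are calibrated once from the base
    inputs and embedded (then Dirichlet-perturbed), so each iteration runs
    without re-calibration.  Draws violating an invariant (for instance a
    remission rate exceeding the response rate) are redrawn up to
    ``spec.max_retries`` times.
    """
    if base.unpublished.biologic_matrices is None:
        base = clone_inputs(base)
        base.unpublished.biologic_matrices = {
            t: calibrate_strategy_matrix(base, t, run_induction(base, t))[0]
            for t in base.strategies
        }
    rel = spec.relative_se
    for _attempt in range(spec.max_retries):
        mi = clone_inputs(base)

        if spec.sample_utilities and rel > 0:
            su = mi.utilities.state_utilities
            for k in su:
                su[k] = _beta_mom(rng, su[k], rel * su[k])
            for ae in mi.utilities.ae_disutilities:
                d = mi.utilities.ae_disutilities[ae]
                mi.utilities.ae_disutilities[ae] = -_beta_mom(rng, -d, rel * -d)

        if spec.sample_costs and rel > 0:
            c = mi.costs
            for d in (c.state_direct_2wk, c.state_indirect_2wk, c.ae_unit_costs):
                for k in d:
                    d[k] = _gamma_mom(rng, d[k], rel * d[k])
            c.surgery_complication_cost = _gamma_mom(
                rng, c.surgery_complication_cost, rel * c.surgery_complication_cost)
            c.soc_drug_cost_2wk = _gamma_mom(
                rng, c.soc_drug_cost_2wk, rel * c.soc_drug_cost_2wk)

        if spec.sample_efficacy and rel > 0:
            for t in mi.strategies:
                e = mi.efficacy[t]
                e.beta_response = _lognormal_odds(rng, e.beta_response, rel)
                e.alpha_remission = _lognormal_odds(rng, e.alpha_remission, rel)
                e.second_dose_response = _lognormal_odds(
                    rng, e.second_dose_response, rel)
                e.second_dose_remission = _lognormal_odds(
                    rng, e.second_dose_remission, rel)

        if spec.sample_event_probs and rel > 0:
            for t in mi.strategies:
                s = mi.treatments[t]
                s.discontinuation_cycle_prob_standard = _beta_mom(
                    rng, s.discontinuation_cycle_prob_standard,
                    rel * s.discontinuation_cycle_prob_standard)
                s.discontinuation_cycle_prob_escalated = _beta_mom(
                    rng, s.discontinuation_cycle_prob_escalated,
                    rel * s.discontinuation_cycle_prob_escalated)
                s.escalation_cycle_prob = _beta_mom(
                    rng, s.escalation_cycle_prob, rel * s.escalation_cycle_prob)
                rts = mi.utilities.ae_cycle_rates[t]
                for ae in rts:
                    rts[ae] = _beta_mom(rng, rts[ae], rel * rts[ae])
            st = mi.settings
            st.annual_surgery_prob = _beta_mom(
                rng, st.annual_surgery_prob, rel * st.annual_surgery_prob)
            st.induction_surgery_prob = _beta_mom(
                rng, st.induction_surgery_prob, rel * st.induction_surgery_prob)
            up = mi.unpublished
            up.surgery_complication_prob = _beta_mom(
                rng, up.surgery_complication_prob,
                rel * up.surgery_complication_prob)

        if spec.sample_matrices:
            up = mi.unpublished
            up.soc_transition_matrix = np.vstack([
                _dirichlet_row(rng, r, spec.matrix_ess)
                for r in np.asarray(up.soc_transition_matrix, dtype=float)
            ])
            up.post_surgery_distribution = _dirichlet_row(
                rng, np.asarray(up.post_surgery_distribution, dtype=float),
                spec.matrix_ess)
            assert up.biologic_matrices is not None
            up.biologic_matrices = {
                t: np.vstack([_dirichlet_row(rng, r, spec.matrix_ess)
                              for r in np.asarray(m, dtype=float)])
                for t, m in up.biologic_matrices.items()
            }

        # the induction split needs beta - (alpha + beta*gamma) >= 0 for
        # both dose stages; independent draws can violate it, so redraw
        g = mi.population.gamma_mod_sev_remainder
        feasible = all(
            e.beta_response - (e.alpha_remission + e.beta_response * g) >= 0
            and e.second_dose_response
            - (e.second_dose_remission + e.second_dose_response * g) >= 0
            for e in (mi.efficacy[t] for t in mi.strategies)
        )
        if feasible and not mi.validate():
            return mi
    raise RuntimeError(
        f"PSA draw failed validation {spec.max_retries} times in a row"
    )


def run_psa(
    base: ModelInputs,
    n_iterations: int = 1000,
    seed: int = 0,
    spec: PSADistributionSpec | None = None,
) -> PSAResults:
    """Probabilistic sensitivity analysis of the incremental outcome.

    Reproducible given (seed, n_iterations, spec): each iteration uses a
    deterministic substream spawned from the seed.
    """
    spec = spec or PSADistributionSpec()
    base = clone_inputs(base)
    if base.unpublished.biologic_matrices is None:
        base.unpublished.biologic_matrices = {
            t: calibrate_strategy_matrix(base, t, run_induction(base, t))[0]
            for t in base.strategies
        }
    streams = np.random.SeedSequence(seed).spawn(n_iterations)
    dc = np.empty(n_iterations)
    dq = np.empty(n_iterations)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        mi = draw_psa_inputs(base, spec, rng)
        res = run_comparison(mi)
        dc[i] = res.incremental.delta_cost
        dq[i] = res.incremental.delta_qalys
    return PSAResults(delta_cost=dc, delta_qalys=dq, seed=seed,
                      n_iterations=n_iterations)
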