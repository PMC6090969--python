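# cdcea

A health-economic model of biologic therapy in moderate-to-severe Crohn's
disease, written for health economists and modellers who need a tested,
scriptable implementation of the two-phase cohort structure used in recent
HTA appraisals of ustekinumab, adalimumab and vedolizumab: a short-term
**induction decision tree** feeding a long-term **Markov cohort maintenance
model** over five health states, with transition-matrix calibration,
societal-perspective costing, QALY accrual, incremental analysis, scenario
analyses and probabilistic sensitivity analysis.

## The model

Disease severity is tracked by CDAI band — remission (CDAI < 150), mild
(150 ≤ CDAI < 220) and moderate-to-severe (220 ≤ CDAI < 600) — plus a
transient surgery state and an absorbing death state.  All patients enter
moderate-to-severe and receive induction therapy; at each assessment the
cohort splits by the remission rate α, response rate β and the fraction γ of
responders who stay moderate-to-severe:

```
remission            α
mild                 β − (α + β·γ)
moderate-to-severe   β·γ
non-response         1 − β
```

First-dose non-responders receive a second induction dose; second-dose
non-responders move to non-biologic standard of care (SoC).  Responders
enter the maintenance phase, simulated in 2-week cycles to a 60-year
horizon: background mortality, surgery (7 % per year, one-cycle stay),
treatment discontinuation from the moderate-to-severe state, optional dose
escalation, and CDAI transitions by a per-cycle 3×3 matrix.  The biologic
matrix is **calibrated** by constrained least squares so that the propagated
cohort hits the end-of-maintenance target distribution supplied by the
external evidence synthesis:

```
minimise  (remission_model − remission_target)² + (mild_model − mild_target)²
```

After the 2-year treatment duration, all patients move to SoC and the
matrix blends linearly into the SoC matrix over a treatment-specific
convergence period.  Costs (drug, administration, health-state resource
use, indirect productivity losses, adverse events, surgical complications)
and QALYs are accrued per cycle and discounted at 3 % per year; strategies
are compared by incremental cost-effectiveness ratio (ICER = ΔC/ΔE) or
dominance, and uncertainty by one-way scenarios and a 1000-iteration PSA
summarised as cost-effectiveness acceptability curves at net monetary
benefit `NMB = λ·ΔE − ΔC`.

Two baseline input bundles ship with the package (2016 EUR): ustekinumab vs
adalimumab in a conventional-care-failure population, and ustekinumab vs
vedolizumab in a TNF-alpha-inhibitor-failure population.  Published inputs
are packaged verbatim; inputs that were never published (SoC transition
matrix, post-surgery distribution, mortality, maintenance targets, some
unit costs) are generated, documented, synthetic stand-ins, flagged via
`provenance_synthetic` and disclosed in every run header.  Base-case
magnitudes therefore characterise the synthetic conditions, not any
published submission.  See `docs/methods.md` for the full account.

## Worked example

```python
import cdcea

inputs = cdcea.paper_baseline_inputs("conventional_care_failure")
result = cdcea.run_comparison(inputs, calibration_seed=1)
print(result.summary_frame().round(1).to_string())
inc = result.incremental
print(f"delta cost: {inc.delta_cost:,.0f} EUR, delta QALYs: {inc.delta_qalys:.3f}")
print(f"ICER: {inc.icer:,.0f} EUR/QALY ({inc.classification})")
```

prints

```
                drug  administration  health_state  indirect  adverse_event  surgery_complication  total_cost  total_qalys  life_years
ustekinumab  66272.8           312.2       62717.3  180682.7          975.5                2159.5    313120.0         16.0        24.5
adalimumab   54560.5           528.2       62950.1  181312.7         1191.6                2166.0    302709.2         15.9        24.6
incremental      NaN             NaN           NaN       NaN            NaN                   NaN     10410.8          0.0         NaN

delta cost: 10,411 EUR, delta QALYs: 0.027
ICER: 378,896 EUR/QALY (icer_reported)
```

Each row disaggregates one strategy's discounted lifetime costs by
component alongside its total QALYs; the final row gives the increments.
Here ustekinumab gains 0.027 QALYs at an extra cost of €10,411 under the
synthetic stand-in inputs — the direction of the QALY gain follows the
efficacy evidence, while the magnitudes are driven by the stand-ins.

The same pipeline is available from the shell:

```
cdcea run src/cdcea/data/conventional_care.yaml --out results/
cdcea owsa src/cdcea/data/conventional_care.yaml --out results/
cdcea psa  src/cdcea/data/tnf_failure.yaml --iterations 1000 --seed 1 --out results/
cdcea calibrate --targets my_targets.yaml --out results/
cdcea synth --population tnf_failure --out inputs.yaml
```

Every command writes CSV tables plus a `manifest.json` (input hashes, seed,
package version) that makes the run reproducible bit for bit.

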