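# fluxcord

Tools for asking *why* a metabolic flux differs between cell lines (or any
sample groups): because the cells express different amounts of the enzyme
(**transcriptional regulation**), because the reaction's substrates are
more or less abundant (**metabolic regulation**), both at once, or neither
detectably. The package integrates transcriptomics and metabolomics with a
constraint-based metabolic model and classifies every reaction it can by
measuring the agreement between three reaction-centric views of the same
network.

## The three datasets and the concordance score

For each group *c*, sample *ξ*, and reaction *r* with gene set *G_r*:

- **RAS (reaction activity score)** pushes expression *T_g* through the
  gene–protein–reaction rule: `AND` operands (enzyme subunits) take the
  minimum, `OR` operands (isoenzymes) the sum, e.g.
  `RAS_r = min{T_g : g ∈ G_r}` for a pure complex. Group means are
  normalized reaction-wise by their maximum over groups, giving
  `RAS̄_r^c ∈ [0, 1]`; reactions without a rule score 1.
- **RPS (reaction propensity score)** is the mass-action substrate product
  `RPS_r = ∏_q [X_q]^{s_rq}` over the reaction's substrates with
  stoichiometric exponents; the unknown kinetic constant cancels in every
  between-group ratio. A reaction with any unmeasured substrate is omitted.
- **FFD (feasible flux distributions)** are flux vectors *v* sampled
  near-uniformly from the polytope `{v : S·v = 0, v_L ≤ v ≤ v_U}` of a
  *cell-relative* model per group, built from three constraint layers:
  1. medium composition scales each uptake bound by the group's relative
     nutrient concentration,
  2. spent-medium measurements add secretion/uptake ratio rows
     `−σ ≤ v_lac − x̄·v_glc ≤ σ` plus a growth-yield bracket
     `minYield·v_glc·mw·10⁻³ ≤ 0.131972·v_bio ≤ maxYield·v_glc·mw·10⁻³`,
  3. each group's flux-variability interval is rescaled by `RAS̄_r^c`.

For every pair of groups each dataset votes −1/0/+1 per reaction (test
p < 0.05 — Welch's *t* for scores, Mann–Whitney *U* for flux samples — and
at least a 20% change of the mean/median). Agreement between two vote
vectors is Cohen's kappa

```
κ = (p_o − p_e) / (1 − p_e)
```

(observed vs chance agreement; 1 = full concordance, −1 = opposite
judgments). A reaction with high RPS-vs-FFD kappa and high RPS-vs-RAS kappa
is under **concerted** control, high RPS-vs-FFD alone is **metabolic
only**, high RAS-vs-FFD alone is **transcriptional only**. Significance of
RPS-vs-FFD scores comes from an empirical null (sign vectors resampled
from the pooled propensity votes), Benjamini–Hochberg adjusted.

## Worked example

A bundled generator builds a toy network (glucose/glutamine core with
lactate/glutamate secretion and independent substrate→product branches)
and matched multi-omics with planted regulation classes:

```python
import fluxcord as fc
from fluxcord.pipeline import PipelineParams, run_pipeline

model = fc.generate_toy_model(n_branches=6)
scenario = fc.default_scenario(model, seed=7)          # planted ground truth
data = fc.generate_planted_omics(model, scenario)

params = PipelineParams(n_samples_total=5000, n_batches=10, thinning=10, seed=7)
result = run_pipeline(
    model, data.expression, data.metabolomics,
    medium=data.medium, spent=data.spent, exchange_map=data.exchange_map,
    biomass_id="BIOMASS", glucose_exchange_id="EX_glc_e", params=params,
)
print(result.concordance.table.loc[[f"BR{i}" for i in range(1, 7)]].round(3))
```

prints

```
     kappa_rps_vs_ffd  kappa_rps_vs_ras  kappa_ras_vs_ffd  p_adjusted                 label
BR1               1.0               NaN               NaN       0.009        metabolic_only
BR2               1.0               NaN               NaN       0.008        metabolic_only
BR3               1.0               1.0               1.0       0.008             concerted
BR4               1.0               1.0               1.0       0.009             concerted
BR5               NaN               NaN               1.0         NaN  transcriptional_only
BR6               NaN               NaN               1.0         NaN  transcriptional_only
```

Reading it: branches whose substrate abundance and uptake bound were
planted to co-vary (BR1–BR2) show perfect flux-vs-propensity concordance
with no activity signal — metabolic control; BR3–BR4 had expression
planted to move too — concerted; BR5–BR6 varied only in expression, so
only the activity-vs-flux kappa is defined and high. A kappa is reported
as missing (`NaN`) when one of its two datasets registered no variation
for that reaction, and the adjusted p-values flag the metabolically
driven reactions at FDR < 5%. `fc.score_recovery(scenario, result.labels)`
confirms all six planted classes are recovered.

The same pipeline runs from the shell on TSV/SBML inputs:

```sh
fluxcord make-fixture --n-branches 6 -o fixture/
fluxcord run-all config.yaml          # ras | rps | build-models | sample | concordance
```

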