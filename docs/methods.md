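# Methods

This note documents the models and procedures implemented in `fluxcord`,
the parameters that matter, the synthetic data the tests run on, and the
numerical choices made where the design was genuinely open.

## Scope and model of the problem

A flux difference between two cell populations can arise from different
enzyme availability (transcriptional regulation), different substrate
availability (metabolic regulation), both, or neither/other causes
(allostery, cofactors, model error). The package does not attempt to
estimate absolute fluxes; it asks only whether the *sign* of the
between-group variation of a reaction's flux agrees with the sign of the
variation of an expression-derived activity score and/or a
metabolomics-derived propensity score. Allosteric and cofactor regulation
would require explicit kinetic modeling and are out of scope.

## Reaction activity scores (RAS)

Per sample, a reaction's GPR rule is evaluated on gene expression with
`AND → min` (the least expressed subunit limits the complex) and
`OR → sum` (isoforms contribute additively), respecting standard operator
precedence. Group scores are sample means; normalized scores divide each
group mean by the reaction's maximum over groups, so exactly one group
scores 1 unless all means are 0 (then all normalized scores stay 0).
Reactions without a rule carry the sentinel score 1, which makes the
transcriptomic constraint layer a no-op for them.

Missing genes (default policy `skip`): a missing `OR` operand is dropped;
a missing `AND` operand leaves the limiting subunit unknown, so the rule
is undefined and the reaction falls back to the sentinel path. The
alternatives `zero` (missing = 0) and `undefined` (any missing gene
undefines the rule) are selectable. Rationale for the default: treating
an unmeasured subunit as zero would close fluxes on no evidence.

Expression units are any non-negative measure (FPKM, counts); no
within-sample renormalization is applied, since all downstream uses are
ratios across groups of the same gene set. Statistical sign tests use the
raw per-sample scores; normalization only rescales group means by a
per-reaction constant and is applied after averaging.

## Reaction propensity scores (RPS)

Under mass action, the rate of an irreversible reaction is
`k_r ∏ [X_q]^{s_rq}` over its substrates. Between two steady states the
kinetic constant cancels, so the bare product tracks how substrate
availability alone would move the flux. Scores are computed on the
irreversible model (forward and reverse partners have different substrate
sets and are scored independently), with `|s_rq|` as exponents; products
never enter. A reaction is *eligible* only if every substrate has a
measured abundance; one missing substrate omits the reaction. Exchange
pseudo-reactions and the biomass reaction are never eligible (no
meaningful substrate pool measurement). A configurable exclusion list can
drop ubiquitous species (a documented `{h2o, h, pi}` preset ships; the
default list is empty — whether such cofactors should count as substrates
is genuinely open, so the default changes nothing silently).

Bulk metabolomics cannot resolve compartments: one measurement (e.g.
citrate) is assigned identically to every mapped compartmental species;
the network structure then decides which compartment's reaction agrees
with the fluxes.

## Cell-relative models

Three incremental constraint layers differentiate one generic model into
per-group models encoding only *relative* differences:

1. **Medium (type 1).** For each exchanged metabolite the group with the
   highest medium concentration receives uptake bound `base_uptake`
   (default 10 flux units — absolute values are arbitrary, only ratios
   matter) and other groups proportionally less; metabolites absent from
   a group's medium cannot be taken up. Secretion bounds are untouched.
2. **Extracellular ratios + growth yield (type 2).** Spent-medium
   concentrations at seeding and after the growth window give
   produced/consumed ratios (lactate/glucose, lactate/glutamine,
   glutamate/glutamine by default). Ratios are averaged over technical
   replicates within each biological replicate; the mean x̄ and sample
   standard deviation σ (ddof = 1; the convention was unspecified, n−1
   chosen as the standard small-sample estimator) over biological
   replicates become the two-sided row `−σ ≤ v_sec − x̄·v_upt ≤ σ`.
   Dividing concentration differences by cell numbers is unnecessary — it
   cancels in the ratio. A growth-yield bracket ties protein output to
   glucose intake in gram units:
   `minYield·u·mw·10⁻³ ≤ 0.131972·v_bio ≤ maxYield·u·mw·10⁻³` with
   `minYield = 3.90762e−5`, `maxYield = 1.67998e−4`, protein fraction
   0.131972 of biomass, and glucose molecular weight 180.16 g/mol (the
   constant was referenced but not printed; the standard value is used).
3. **Transcriptomics (type 3).** Per group, flux variability analysis
   (paired LPs, no biomass objective, yield bracket retained) gives each
   reaction's attainable interval `[v_L^c, v_U^c]` under layers 1+2; for
   GPR-bearing reactions the interval is rescaled to
   `[RAS̄·v_L^c, RAS̄·v_U^c]`, so the group with the top activity score
   spans the full range and others are proportionally narrowed. GPR-less
   reactions and a configurable exemption list (for cases where a null
   score would wrongly abolish growth, e.g. essential transporters whose
   transcripts fall below detection) keep the plain interval.

Ordering is load-bearing: ratio rows are stated on net exchange fluxes
and must be attached *before* the reversible→irreversible split (the
split rewrites each row onto forward-minus-reverse variables); FVA runs
*after* the split so that scaling acts on non-negative per-direction
bounds and is not inflated by futile-loop artifacts. Layers can be
toggled; omitting type 2 and applying type 3 directly after type 1 is
supported. SBML cannot embed the linear rows, so models are written as
SBML L3+fbc plus a JSON sidecar.

## Flux sampling

The feasible region is parametrized by an orthonormal basis of the null
space of the stoichiometry plus all implicit equalities (rows whose two
sides coincide, e.g. a ratio row with zero replicate spread, and
fixed-bound variables). In those coordinates an artificial-centering
hit-and-run chain runs: directions pass through a randomly chosen stored
point (warm-up vertex or previously recorded sample) and the running
center; the chord through the current point is intersected with every
bound and constraint row and the next state is uniform on it. The
direction archive is seeded with the min/max flux-variability vertex
solutions of every free reaction — flux polytopes are severely
anisotropic (the yield bracket is ~10⁴ times narrower than an uptake
range) and isotropic directions mix impractically slowly; vertex-seeded
centering is the same device the established samplers in this field use.

Samples are recorded every `thinning` accepted steps (default 10) after
discarding `thinning × 100` warm-up steps per batch; batches (default 10)
run independent chains whose seeds derive from the master seed by a
counter, so a sample set is reproducible from (model, parameters, seed).
A zero-volume polytope returns its single vertex repeated, with a
warning. Production-scale runs mirror a 10 × 100,000 batch protocol; the
test suite uses 5,000–50,000 samples per group, which the toy fixture's
~20-dimensional polytopes mix well within (verified by the uniformity
and batch-stability tests). Every emitted sample set can be re-validated
against `S·v = 0`, bounds, and all extra rows at tolerance 1e−6.

The in-silico growth yield of a sample is
`0.131972·v_bio / (u_glc·mw·10⁻³)` (protein grams per glucose gram per
hour); the summary statistic is the median over samples with glucose
uptake above tolerance.

## Concordance and classification

Per reaction and per lexicographically ordered group pair, each dataset
votes −1/0/+1: a vote requires test p < 0.05 *and* at least a 20%
fold-change of the central value. RAS/RPS use Welch's t-test (unequal
variances is the safe choice at n = 3) on per-sample scores with the
mean as central value;
flux distributions use the two-sided Mann–Whitney U test with the median.
U-test p-values at 10⁶ samples are degenerate (any microscopic shift is
"significant"), so each group is down-sampled to at most `max_test_n`
(default 10,000) evenly strided values before testing; the 20% fold
guard does the real gating. The thresholds 1.2/0.8 are applied literally
and asymmetrically on the ratio.

Cohen's kappa compares two vote vectors: κ = (p_o − p_e)/(1 − p_e) with
chance agreement from the two marginal distributions. Degenerate cases:
two constant vectors score 1 when equal and −1 when different. At the
*classification* layer a kappa is treated as missing when either vote
vector is all-zero: a rater that registered no variation anywhere carries
no agreement information, and without this rule a pair of all-zero
vectors would count as perfect concordance and a no-effect experiment
would not come out inconclusive.

Labels (threshold 0.2, "fair concordance"): `concerted` when both
RPS-vs-FFD and RPS-vs-RAS exceed it; `metabolic_only` when RPS-vs-FFD
exceeds it but RPS-vs-RAS does not (or is missing — GPR-less reactions
have no activity score by construction); otherwise `transcriptional_only`
when RAS-vs-FFD exceeds it; otherwise `other` if any kappa exceeds it in
magnitude; else `inconclusive`. RAS-vs-FFD is reported but never drives
significance: the flux samples were constrained with the activity scores,
so those two datasets are not independent.

Significance of RPS-vs-FFD: sign vectors are resampled (default 1000
draws, with replacement) from the pooled empirical distribution of
propensity votes across all eligible reactions and pairs — resampling
votes rather than raw scores avoids over-representing zeros — and scored
against each reaction's flux votes; `p = (1 + #{κ_null ≥ κ_obs})/(1 + n)`
(add-one, avoiding exact zeros), Benjamini–Hochberg adjusted across
reactions. Pooling is pooled-by-default with a per-reaction option; the
construction is ambiguous in the source methods family and the choice is
surfaced as a parameter rather than hidden.

## Synthetic fixtures and what they show

The toy network grafts independent uptake→transport→conversion branches
onto a glucose/glutamine core with lactate/glutamate secretion, a
reversible reaction, mixed AND/OR rules, a GPR-less transporter, a
cytosol/mitochondrion duplicated metabolite, and a biomass reaction, so
every pipeline stage (medium scaling, ratio rows, yield bracket,
splitting, FVA, activity scaling, sampling, concordance) is exercised.
Catabolic drain reactions are included deliberately: without them
stoichiometry would force secretion/uptake ratios of exactly one and the
planted spent-medium ratios (lactate/glucose 1.5, lactate/glutamine 5,
glutamate/glutamine 0.8) would pin all uptakes at zero.

Planting: each branch's conversion reaction is assigned a class; group
multipliers (a rotation of 1/2/4, every pairwise ratio a factor 2) are
applied to enzyme expression (transcriptional/concerted) and/or substrate
abundance plus medium concentration (metabolic/concerted). Per-sample
values are lognormal around the group means (noise sd 0.1, 3
samples/group, 3 groups by default — three groups keep tests fast while
still giving 3 pairwise comparisons); spent-medium replicates get 3%
scatter. Everything is deterministic given the scenario seed.

The zero-effect scenario sets every multiplier to 1 and uses noise sd
0.05 by design: the 20% fold guard sits >4σ from the null mean-ratio
there, so false votes are negligible and the expected outcome — all votes
zero, every reaction inconclusive — is a property of the method, not of a
lucky seed. At sd 0.1 with n = 3 the guard is only ~2.2σ out and a few
false votes per several dozen reactions are statistically inevitable;
that regime is exercised by the planted-recovery test instead, whose
criterion (≥80% of planted metabolic and concerted reactions recovered)
tolerates them.

What the fixture does *not* emulate: realistic kinetics, correlated
noise across genes/metabolites, compartment-specific measurements,
thermodynamic infeasibilities, or genome-scale polytope geometry — so
passing tests demonstrate correctness of the machinery and recoverability
of planted signals at toy scale, not performance on real genome-scale
data, where sampling convergence is the binding concern.

## Numerical choices and limitations

- LPs (FVA, feasibility, interior points, warm-up vertices) use HiGHS
  via scipy; FVA bounds with |v| < 1e−9 are clipped to zero and
  min/max are reconciled against solver jitter.
- Constraint rows with upper−lower ≤ 1e−12 are treated as equalities and
  absorbed into the null-space parametrization.
- Sample validity tolerance is 1e−6 throughout (steady state, bounds,
  rows); the chain's incremental constraint evaluations are refreshed
  every 1000 steps to curb floating-point drift.
- Group pair order is lexicographic and shared across datasets; pair
  vectors are compared positionally.
- Known limitations: per-direction scoring means a reversible reaction
  contributes two rows whose propensities share metabolites; the
  empirical null treats pairs as exchangeable; t-tests at n = 3 have
  little power, which the relaxed 20% fold threshold partially offsets
  (a deliberate trade-off inherited from the method family).
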