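# Methods

This note documents the models and numerical choices behind `metsnet`,
in the order the pipeline uses them.

## Disease staging

Each subject-wave is scored on five binary Joint Interim Statement
components: waist circumference ≥ 85 cm (men) / ≥ 80 cm (women); SBP
≥ 130 mmHg **or** DBP ≥ 85 mmHg or treated hypertension; fasting glucose
≥ 5.6 mmol/L or treated hyperglycemia; triglycerides ≥ 1.7 mmol/L; HDL-C
< 1.03 mmol/L (men) / < 1.29 mmol/L (women) or treated. Boundary values
equal to a ≥ cut point qualify; the HDL criterion is a strict `<`. The
blood-pressure criterion is read as the OR of its two limbs (the
conventional JIS reading of the "130/85" shorthand). The abnormal count
maps to four ordered states (FMD 0, MMD 1, SMD 2, MetS ≥ 3); comparing
the two waves under that order yields forward / reverse / unchanged
transition labels. Subjects with an unevaluable criterion (missing
measurement and no qualifying treatment flag) are excluded from staging
(complete case) rather than imputed.

Two analysis populations are derived for network modelling: the
*progression* model uses subjects below MetS at baseline with outcome
∈ {unchanged, forward}; the *recovery* model uses subjects above FMD at
baseline with outcome ∈ {unchanged, reverse}. Opposite-direction movers
are excluded from each model, so each binary outcome is a genuine
conditional within its at-risk population. The rule is a package
decision (the source tables do not pin it down) and is implemented in
one place (`mets.analysis_subset`) so it can be changed coherently.

## Network model and parameter estimation

Networks are discrete: a DAG over categorical variables with one CPT per
node and joint `P(x) = ∏ᵢ P(xᵢ | pa(xᵢ))`. CPT rows are stored
normalized; construction rejects rows whose sum deviates from 1 by more
than 1e-6 unless normalization is requested explicitly (one published
recovery-CPT row sums to 100.30% and is renormalized that way).
Parent-level combinations are enumerated row-major in the parents'
declared level orders; this ordering is part of the JSON serialization
contract, so identical networks serialize byte-identically. The number
of possible structures on n labeled nodes uses Robinson's recurrence
`a(n) = Σᵢ (−1)^{i+1} C(n,i) 2^{i(n−i)} a(n−i)` in exact integer
arithmetic, validated against brute-force enumeration up to n = 4.

CPTs are estimated by the Dirichlet posterior mean
`θ̂ᵢⱼₖ = (Nᵢⱼₖ + αᵢⱼₖ)/(Nᵢⱼ + Σₖ αᵢⱼₖ)` with a uniform BDeu-style prior
`αᵢⱼₖ = iss/(rᵢ qᵢ)`. The default imaginary sample size is **iss = 1**:
the cited software family's default, weak enough to be irrelevant at
cohort scale (it shifts an entry by < 1/Nᵢⱼ) while guaranteeing strictly
interior probabilities. Counting is complete-case *per node family*
(a row missing one covariate still informs every family it is complete
for); a whole-row rule can be had by dropping incomplete rows upstream.
Empty families return the uniform prior mean.

## Structure learning

Hill climbing over add/delete/reverse single-arc moves, scored by the
decomposable multinomial BIC
`Σᵢ Σⱼₖ Nᵢⱼₖ log(Nᵢⱼₖ/Nᵢⱼ) − (log N / 2) Σᵢ qᵢ(rᵢ−1)` (0·log 0 ≡ 0).
BIC is the score because the method's toolkit family defaults to it; the
scorer is pluggable. Search starts from the whitelist-only graph, never
violates the blacklist, never deletes a whitelist arc, never creates a
cycle, and stops at a local optimum (no restarts — a documented
limitation of plain hill climbing; bootstrap averaging is the robustness
mechanism instead). Equal-score moves break ties lexicographically by
(move type, parent, child), making the search fully deterministic.

Bootstrap model averaging redraws the n rows with replacement B times,
re-runs the hill climb, and aggregates per node pair: *strength* = the
fraction of replicates containing the arc in either direction,
*direction* = among those, the fraction orienting it a given way (the
bnlearn-style convention: the strength threshold applies to the
undirected arc, the direction threshold to its orientation). The
averaged network keeps arcs with strength ≥ 0.85 (inclusive) oriented
where direction > 0.5, breaking an exact tie toward the
lexicographically smaller parent, and drops cycle-inducing arcs in
increasing strength order. Replicate r's resampling stream is keyed by
(master seed, r), so enlarging B extends the replicate sequence instead
of reshuffling it.

## Inference

`query` performs exact variable elimination: evidence is sliced out of
the CPT factors, only ancestors of the target and evidence are kept, and
hidden variables are eliminated in min-degree order over the moralized
interaction graph (ties lexicographic — the order affects speed, never
values). Evidence whose probability is zero raises a dedicated error
rather than returning a 0/0 artifact. `enumerate_posterior` is the
deliberately naive full-joint oracle; the test suite drives both engines
over the fixtures and a thousand random networks of up to 10 nodes and
requires agreement within 1e-12.

*Causal reasoning* instantiates one factor level as hard (100%) evidence
and tabulates the outcome posterior against the no-evidence prior;
*evidential reasoning* conditions on an outcome level and tabulates each
factor's posterior with ↑/↓ markers. Soft/virtual evidence is out of
scope. Raw probabilities are kept unrounded; rendered tables round
half-up to 2 decimals of percent.

## Published-network fixtures

The progression and recovery networks ship with their published priors
and outcome CPTs. The intermediate tables the publication does not print
— P(hyperuricemia | gender) and P(BMI | age or gender, exercise) — are
reconstructed as zero-sum tilts of the published child marginal with
parent scores centred under the published root marginals, so the implied
child marginals equal the published priors *exactly* while the effect
directions follow the published qualitative findings (men have roughly
twice the hyperuricemia risk; older age, less exercise and male sex
shift mass toward overweight/obesity). The tilt magnitudes are synthetic
plumbing: outcome inference is provably insensitive to them because the
outcome depends only on its two parents, whose distributions are pinned.

## Synthetic cohort generator

The generator emulates a two-wave ageing-cohort biomarker file.
Covariates are drawn from the published priors (with the
gender → hyperuricemia and age/exercise → BMI dependence above); smoke,
drink and functional-loss prevalences (28%, 24%, 20%) are invented, as
those marginals are not published and the nodes are d-separated from the
outcomes. Baseline biomarkers are sex-specific log-normals shifted on
the log scale by covariate effects (overweight raises waist, TG, FBG,
SBP and lowers HDL; etc.). Locations and effect sizes are plumbing,
calibrated once so every component prevalence lies in a plausible
10–50% band; nothing downstream depends on their specific values.

Transitions are drawn as **competing moves**: a progression propensity
from the published progression CPT (given hyperuricemia and BMI; only if
below MetS) and a recovery propensity from the recovery CPT (given HbA1c
and BMI; only if above FMD), as independent Bernoulli draws with
simultaneous moves rejected. That construction preserves each CPT
exactly within its own analysis population — conditioning on "did not
move the other way" recovers the configured conditional — which is what
makes parameter- and structure-recovery tests well-posed. Follow-up
biomarkers are then *constructed* to realize the drawn transition: a
target component count is chosen (one state up or down; entry into MetS
draws 3–5 components), unlocked components are flipped at random
(treatment flags lock their component on), and each biomarker is drawn
on the required side of its cut point. Subjects whose transition is
infeasible (treatments lock more components than the target allows) are
regenerated from fresh randomness. All generators are bit-reproducible
under a fixed seed.

What the generator does **not** emulate: survey weights, attrition,
measurement error, within-subject biomarker correlation beyond the
shared covariate shifts, and treatment initiation between waves.
Passing recovery tests therefore demonstrate correctness of the
estimators under the assumed generating structure, not robustness to
those real-data complications.

## Problem sizes and known limitations

The test suite scales the expensive stages to sizes that keep the whole
run in minutes while leaving each check well-powered: oracle equivalence
uses 1,000 random networks capped at 1,024 joint states; parameter
recovery refits on 50,000 forward samples; bootstrap structure recovery
uses B = 200 replicates over 10,000 rows (the headline analysis would
use B = 10,000 — strength estimates at B = 200 have a Monte-Carlo SE
below 0.035 near the 0.85 threshold, ample for arcs whose support is
near 1). One caveat is recorded rather than hidden: at 50,000 samples
the rare hyperuricemia × thin parent cell holds only ~240 rows, so its
CPT entry cannot be pinned to ±0.01 by any unbiased estimator (binomial
SD ≈ 0.014); the per-row 3σ consistency check is the statistically
meaningful recovery guarantee. Exact inference and enumeration are
exponential in treewidth and state space respectively — fine for the
≤ 10-node epidemiological networks here, not for high-dimensional use.
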