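# metsnet

Discrete Bayesian networks for the **bidirectional progression of
metabolic syndrome (MetS)** in two-wave longitudinal cohorts.

Metabolic syndrome is diagnosed when at least three of five metabolic
components are abnormal (central obesity, elevated blood pressure,
elevated fasting glucose, hypertriglyceridemia, low HDL-C, per the Joint
Interim Statement). Between survey waves a person can *progress* toward
MetS or *recover* away from it, and the epidemiological question is which
risk factors drive each direction. `metsnet` is for epidemiologists and
biostatisticians who want to model that question with discrete Bayesian
networks: it stages subjects, learns a network over the candidate risk
factors, and quantifies factor effects by exact probabilistic inference.

## What is inside

- **JIS staging** (`metsnet.mets`): the five component criteria with
  sex-specific cut points, the four ordered disease states
  FMD (0 abnormal) < MMD (1) < SMD (2) < MetS (≥3), forward / reverse /
  unchanged transition labels, and cohort transition accounting.
- **Network model** (`metsnet.network`, `metsnet.io`): categorical
  variables, DAGs, CPTs, the joint factorization
  `P(x₁,…,xₙ) = ∏ᵢ P(xᵢ | pa(xᵢ))`, validation, JSON + BIF serialization,
  and the labeled-DAG count `a(n) = Σᵢ (−1)^{i+1} C(n,i) 2^{i(n−i)} a(n−i)`.
- **Structure learning** (`metsnet.structure`): BIC-scored hill climbing
  under whitelist/blacklist arc constraints, plus nonparametric bootstrap
  model averaging — arcs kept when their bootstrap strength is ≥ 0.85 and
  oriented by a 0.5 direction threshold.
- **Parameter learning** (`metsnet.params`): Dirichlet posterior-mean
  CPT estimation, `θ̂ᵢⱼₖ = (Nᵢⱼₖ + αᵢⱼₖ) / (Nᵢⱼ + Σₖ αᵢⱼₖ)` with a
  BDeu-style uniform prior (`αᵢⱼₖ = iss / (rᵢ qᵢ)`, default iss = 1).
- **Exact inference** (`metsnet.inference`): variable elimination,
  a brute-force enumeration oracle it is property-tested against,
  *causal reasoning* (instantiate a factor at 100%, read the outcome
  posterior) and *evidential reasoning* (condition on the outcome, read
  each factor's posterior — the Bayes inversion).
- **Synthetic cohorts** (`metsnet.simulate`): forward sampling from any
  network and a biomarker-level two-wave cohort generator, so the whole
  pipeline is testable without access to restricted survey data.
- **Published networks** (`metsnet.fixtures`): the progression network
  (hyperuricemia and BMI level as direct parents of the outcome; gender,
  age and exercise acting through them) and the recovery network (high
  HbA1c and BMI level as direct parents), with the published priors and
  outcome CPTs.
- **sklearn estimators** (`metsnet.estimators`):
  `BayesianNetworkClassifier` (fit = structure + parameter learning,
  `predict_proba` = row-wise posterior) and the `MetsStager` transformer.
- **CLI** (`metsnet`): `simulate`, `classify`, `learn`, `fit`, `infer`,
  `report`, `run`.

## Worked example

```python
from metsnet import build_published_fixture, query, evidential_reasoning

net = build_published_fixture("progression")
print(f"P(forward)                    = {100 * query(net, 'progression')[1]:.1f}%")
print(f"P(forward | hyperuricemia=yes) = {100 * query(net, 'progression', {'hyperuricemia': 'yes'})[1]:.1f}%")
print(f"P(forward | BMI=overweight)    = {100 * query(net, 'progression', {'bmi': 'overweight'})[1]:.1f}%")
table = evidential_reasoning(net, "progression", "forward", ["hyperuricemia"])
print(table.rounded()[["variable", "level", "prior", "posterior", "trend"]])
```

prints

```
P(forward)                    = 35.9%
P(forward | hyperuricemia=yes) = 60.0%
P(forward | BMI=overweight)    = 40.9%
        variable level  prior  posterior trend
0  hyperuricemia    no  91.59      85.93     ↓
1  hyperuricemia   yes   8.41      14.07     ↑
```

Reading: in this population about 36% of at-risk subjects progress
toward MetS; hard evidence of hyperuricemia raises that to 60%, being
overweight/obese raises it to 41%. Inverting the reasoning, subjects who
did progress are markedly enriched for hyperuricemia (8.4% → 14.1%).

The same pipeline end-to-end on a synthetic cohort:

```bash
metsnet run --outcome progression --n 20000 --boot 200 --seed 7 --outdir out/
```

writes the staged cohort, the bootstrap arc-strength table, the averaged
network (JSON + BIF), the fitted outcome CPT and both reasoning tables.

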