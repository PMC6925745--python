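# accidentbn

Discrete Bayesian-network analysis of occupational-accident risk from
categorical working-conditions surveys.

The package targets the setting of the 7th Spanish National Survey of
Working Conditions (VII NSWC): 8892 surveyed workers, reduced to 8880
after dropping the 12 who did not answer the accident question, recoded
into 29 categorical variables — a binary accident indicator `V1`, a
4-level production sector `V2`, and demographic, employment, safety,
hygiene, ergonomic and psychosocial conditions, the last six of which
(`V24`–`V29`) are 5-level Likert variables obtained by collapsing
multi-item questionnaire blocks with a Cronbach-alpha reliability check.

## The model

A discrete Bayesian network over the survey variables factorises the
joint distribution as

P(V1, …, V29) = ∏ᵥ P(v | pa(v)),

with one conditional probability table (CPT) per node. The package
provides:

- **Estimation** — multinomial maximum likelihood with a Laplace
  pseudo-count `a`: P(v=c | pa=π) = (N(c,π)+a) / (N(π)+a·K).
- **Structure learning** — greedy hill-climbing over add/delete/reverse
  edge moves maximising BIC = log L − (log n / 2)·(free parameters),
  with optional edge white/blacklists and random restarts.
- **Exact inference** — variable elimination (min-degree order), giving
  P(accident | evidence) for any evidence configuration.
- **Sensitivity analysis** — evidence sweeps over one variable
  (optionally within a sector) or two variables jointly, reported as
  conditional accident percentages and signed deltas versus the
  a-priori baseline, with support-based suppression of rare categories
  (e.g. physical effort "always", observed 24 times, is dropped).
- **Validation** — 10-fold cross-validated ROC/AUC of the network as
  an accident scorer, each held-out worker scored as
  P(V1 = yes | all other recorded variables).
- **A synthetic-survey generator** — a ground-truth network calibrated
  by exact inference to the published marginal frequencies (accident
  prior 7.38%), with configurable risk-multiplier effects, used for
  every simulation test and recovery experiment. No microdata ship
  with the package.

## Worked example

```python
import accidentbn as ab
from accidentbn.report import render_sensitivity
from accidentbn.simulate import (
    default_generator_spec, build_ground_truth, sample_survey, mask_exact,
)

spec = default_generator_spec(seed=1)
truth = build_ground_truth(spec)                       # calibrated ground truth
survey = mask_exact(sample_survey(truth, 8892, seed=1), "V1", 12, seed=2)

model = ab.AccidentRiskModel(survey)                   # drops the 12 non-responses
results = model.fit()                                  # learn DAG + CPTs
print(results.summary())
print(render_sensitivity([results.one_variable_sweep("V24")], "text"))
roc = results.cross_validate()
print(f"pooled AUC {roc.auc:.3f}")
```

prints

```
Accident-risk Bayesian network
======================================
records (after target filtering): 8880  (dropped 12)
nodes: 29   edges: 5
target: V1 (yes)   sector: V2
BIC: -232295.2
a-priori P(V1=yes): 7.89%
direct neighbors of V1: V24, V27, V28
edges:
  V1 -> V24
  V1 -> V27
  V2 -> V24
  V27 -> V2
  V28 -> V1

target V1=yes  baseline 7.89%
     V24 % ACC % VAR  support
   often 17.80 +9.91      264
at times 13.32 +5.44     1790
  rarely  6.85 -1.04     4446
   never  4.24 -3.65     2356

pooled AUC 0.656
```

Reading the output: the learned graph links the accident node directly
to physical effort (`V24`) and personal development (`V27`) — the
generator's designed dependency structure (edge orientation within a
Markov-equivalence class is not identifiable from data). The sweep
says a worker reporting physical effort "often" has a 17.80% accident
probability, +9.91 points over the 7.89% baseline; "always" is absent
because it falls below the 25-record support threshold. The pooled AUC
is the discrimination of the scorer over all 8880 held-out predictions;
its value is a property of the synthetic generator's effect sizes, not
of the real survey.

A command-line interface wraps the same pipeline:

```bash
accidentbn run --n 8892 --seed 1 --k 10 --out-dir runs/demo
```

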