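# Methods

## Data model

A survey is a table of n workers by 29 categorical variables bound to a
codebook. Category codes are 1-based integers in the on-disk CSV; DK/NA
("do not know / no answer") is the dedicated sentinel code 0, never an
empty cell, so structural non-response is distinguishable from file
corruption. The bundled codebook carries the published VII NSWC
category sets and marginal counts (every row sums to the 8880 analysed
workers, DK/NA included). DK/NA is declared only for the variables that
listed it in the survey; the six 5-level study variables and the
accident target have none.

Two conventions follow from this. First, a *raw* table may carry the
sentinel on any variable (the field sample had 12 accident
non-responses); whether DK/NA is *modelled* is decided by the codebook
at estimation time, where an undeclared sentinel is an error. Second,
for declared variables DK/NA is an ordinary extra category of the
network — the published frequency table treats it as one — so no rows
are discarded during counting. Accident non-responses are dropped once,
up front (8892 → 8880); the filter touches only the target column and
is idempotent.

Report percentages are rounded half-up at render time only (one decimal
for the composition table, two for sweeps); machine-readable outputs
keep full precision.

## Item aggregation and reliability

Each study variable condenses a block of questionnaire items answered
on one shared 5-level frequency scale (no reverse-scored items).
Internal consistency is Cronbach's alpha with unbiased (n−1) variances,
computed on listwise-complete rows — alpha needs a complete covariance.
Labels: α ≥ 0.70 "acceptable" (the survey's own reliability floor),
α ≥ 0.90 "excellent" (a conventional cut, flagged as such). A block
with zero total variance or fewer than two complete rows is a reported
error, isolated per block in the reliability report.

How the original analysis collapsed items into one 5-level code is not
documented, so the rule here is an explicit package choice: the
arithmetic mean of the *available* item codes, rounded half-up to the
nearest integer in 1..5 (a 2.5 tie maps to 3); a fully missing record
gets DK/NA. Mean-of-available avoids discarding workers at the
aggregation step, preserves the scale and its ordering, and is monotone
(raising an item never lowers the aggregate). The rule is isolated in
one function and swappable.

## Network estimation

CPTs are multinomial maximum likelihood with a Laplace pseudo-count,
default 1. Smoothing keeps rarely observed parent configurations
(physical effort "always" co-occurring with anything is a handful of
rows) away from degenerate 0/1 estimates that would destabilise
evidence sweeps; with pseudo-count 0, an unseen configuration falls
back to a uniform row, and an empty table is an error. One consequence
worth naming: the smoothed network's a-priori accident probability sits
slightly below the raw empirical rate whenever the target is rare —
shrinkage toward uniform within parent configurations, averaged over a
skewed parent distribution, moves the implied marginal. The original
study's prior (7.38%) also sits below its empirical rate (686/8880 =
7.73%), which is consistent with some form of smoothing or model
marginalisation in the original tooling; the package does not attempt
to reproduce 7.38% on real data exactly.

Structure learning is greedy BIC hill-climbing: all add/delete/reverse
moves are enumerated in sorted order each iteration, the best strictly
improving move is applied, and family scores are cached (BIC is
decomposable). `max_parents` defaults to 3 — at 29 nodes with 5-level
variables, an unbounded parent set inflates CPTs past what 8880 rows
support. Acyclicity is enforced at every step; determinism is by
construction (sorted enumeration, first-best tie-break) with random
restarts derived from a single integer seed. Forced and forbidden edge
lists support partially constrained learning.

## Inference

Exact posterior queries use variable elimination: evidence is applied
by slicing factor arrays, hidden variables are summed out in min-degree
order over the moralized factor graph with ties broken by variable id
(deterministic and adequate at 29 nodes), and the surviving factor over
the query variable is renormalized. Evidence with zero probability
raises an explicit impossible-evidence error rather than producing
NaNs. Held-out scoring in cross-validation uses the algebraic shortcut
that with evidence on every non-target variable only the target's CPT
and its children's CPTs survive normalization; the vectorised scorer is
tested record-by-record against generic variable elimination.

## Sensitivity analyses

The a-priori accident probability is the no-evidence posterior of the
target. One-variable sweeps report, per category, the conditional
accident percentage and its signed delta; the baseline is the global
prior. Sector-stratified tables condition every cell on the sector as
well, and their deltas are taken against the *matching sector's* prior
— this is the convention under which the published per-sector increases
(e.g. 12.15 − 9.86 = +2.29 in industry) are internally consistent.
The "Total" column is the unconditioned sweep.

Categories observed fewer than `min_support` times (default 25) are
suppressed from sweeps; the default reproduces the published exclusion
of physical effort "always" (24 respondents). In two-variable grids a
cell whose evidence combination has training support below the
threshold — or probability zero under the network — is reported as a
dash rather than a number; a dash means "not estimable", not "zero
risk". Deltas always satisfy p − delta = baseline exactly before
rounding.

## Cross-validated ROC/AUC

Records are shuffled once (seeded) and split contiguously into k = 10
folds whose sizes differ by at most one; at n = 8880 every fold holds
exactly 888 records against 7992 for training. Per fold, structure and
parameters are relearned from scratch on the training folds. ROC points
and the trapezoidal area go through scikit-learn's curve machinery; with
ties given half credit the area equals the Mann–Whitney rank statistic
divided by n₁·n₀, an identity the tests enforce to 1e-12 against an
independent rank-based computation. "Average AUC" is ambiguous between
mean-of-folds and pooled-over-merged-predictions, so both are reported
side by side; a fold lacking one class yields an undefined fold AUC
while the pooled value is still computed.

## The synthetic generator

The generator exists because the official microdata are not bundled: it
builds a *known* network over the full codebook so that every analysis
step, and the learner's ability to recover structure and parameters,
can be tested end to end.

Marginals: each variable's target distribution is the published
marginal (DK/NA included as a category where declared), except the
accident target, which is calibrated to the published a-priori 7.38%
rather than the empirical 7.73% — the two differ in the source analysis
and the prior is the quantity the sweeps are anchored to. Dependencies
are expressed as risk multipliers: the CPT column for child category c
under parent state p is proportional to baseline_c · M[p, c], effects
from several parents multiplying. Baselines are tuned by a
multiplicative fixed-point update (baseline ← baseline · target /
implied, with the implied marginal computed by exact inference over the
already-built ancestors) until every category matches its target to
1e-9 — a bisection-equivalent 1-D odds search for binary children that
generalises to 5-level ones. An unattainable target is a reported
error naming the variable.

The default dependency structure is sector → physical effort, sector →
personal development, and physical effort / personal development /
independence / concerns → accident: the qualitative neighborhood of the
published graph, with all other variables independent roots. Effect
sizes are set from the printed tables where they identify them and from
detectability arithmetic where they do not:

- physical effort: 8/5.5/3.5/2/1 on the accident odds, matching the
  published marginal sweep span (16.59% "often" vs 3.48% "never",
  odds ratio ≈ 5.5);
- personal development: 1/1.45/2.1/3.3/5.5 — deliberately far steeper
  than the published *marginal* sweep (6.74–8.69%), because the
  published *joint* sweep shows the real contrast (12.23% vs 49.36%
  overall, up to ~13× by sector) and because a variable designated as
  directly linked must carry enough signal to be found: a 5-level
  parent joining a binary target that already has one 5-level parent
  must clear a BIC penalty of ≈ (log n / 2) · 20 ≈ 99 nats at
  n = 20000, and a 4× span does not clear it reliably;
- independence and concerns: spans of ~2.2–2.5×, "weak" relative to the
  above but above the child-edge detection threshold (≈ 20 nats);
- sector effects tilt physical effort and development enough to make
  sector priors heterogeneous, as in the published per-sector table.

What the generator does **not** emulate: the real survey's full joint
dependence (only six designed edges exist; everything else is
independent), item-level structure within question blocks, informative
non-response (masking is independent per cell), or survey weighting
(the source analysis applied none either). Passing simulation tests
therefore demonstrates the *machinery* — calibration, learning,
inference, sweeps, validation — not agreement with the real survey's
absolute numbers; the published absolute sweep cells and the real-data
AUC of 0.816 require the official microdata and are out of scope. On
the default generator the cross-validated pooled AUC is ≈ 0.65, a
property of the designed effect sizes.

## Problem sizes and numerics

The test suite runs recovery at n = 20000 over 20 seeds, the inference
oracle over 200 random ≤6-node networks against full-joint enumeration
(tolerance 1e-12), the AUC identity over 200 tie-rich instances
(1e-12), and calibration by exact inference (1e-3 per category); the
acceptance script uses the survey-scale n = 8892/8880 pipeline with
k = 10. CPT rows must sum to 1 within 1e-9; serialized networks store
probabilities at 12 significant digits and round-trip byte-stably. All
randomness flows from explicit integer seeds; identical configurations
are byte-reproducible.

## Known limitations

- Edge orientation is only identified up to Markov equivalence; reports
  should read the learned graph's skeleton and neighborhoods, not
  individual arrowheads.
- The maximum CPT recovery error is dominated by near-unobservable
  parent configurations (rare-category combinations) and does not
  shrink visibly with n; the mean error does.
- Hill-climbing is a local search; restarts mitigate but do not remove
  local optima.
- Cronbach's alpha assumes tau-equivalent items on an interval-like
  scale; no ordinal alpha or factor-analytic alternative is provided.
- The evidence sweeps are conditional probabilities, not causal
  effects; no do-calculus interpretation is intended.
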