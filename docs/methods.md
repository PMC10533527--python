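# Methods

`svbn` quantifies how binary clinical, demographic, and genetic risk factors
combine — possibly synergistically — to shift the probability of adverse
neurodevelopmental and growth outcomes in an infant cardiac cohort, using
discrete Bayesian networks. This note documents the model, the algorithms,
the defaults, and the limits of what the validation battery shows.

## The model

All analysis variables are binary after dichotomization. A Bayesian network
over variables `X_1..X_k` is a directed acyclic graph (DAG) plus one
conditional probability table (CPT) per node, factorizing the joint as

    P(x_1, ..., x_k) = prod_v P(x_v | x_pa(v)).

Edges encode conditional dependence, not causation; every risk quantity the
package reports is a conditional-probability functional of this joint.

### Structure score and search

Structures are scored with the decomposable BIC in natural-log units,

    score(G) = sum_v [ LL_hat(v | pa(v)) − 0.5 · ln(N) · k_v ],

where `LL_hat` is the maximized multinomial log-likelihood of the child
within each parent configuration (`0 · ln 0 ≡ 0`) and
`k_v = (|states(v)| − 1) · prod |states(pa)|`. Larger is better. No
smoothing enters the score (pure MLE, the standard convention); smoothing
would double-penalize sparse families on top of the BIC term.

The search is exact, not heuristic: dynamic programming over variable
subsets — best parent set per (node, candidate set), then best sink per
subset, then order reconstruction. Its result provably attains the maximum
score over all DAGs respecting the parent cap, which the test suite verifies
against brute-force enumeration of all 543 four-node DAGs. The node guard is
20 (memory/time grow as `n · 2^n`); `max_parents` defaults to 3 — the cohort
networks have ≤10 nodes, so exact search stays comfortable while the cap
keeps CPTs estimable. Markov-equivalent DAGs tie under BIC exactly; scores
within 1e-9 are treated as tied and broken deterministically (fewer parents
per family, lexicographically smaller parent sets, lexicographically smaller
sink), so repeated runs and row permutations return the same DAG.

### Parameters

CPTs are Dirichlet posterior means, `(count + α) / (total + α · |states|)`,
with uniform prior weight `α` (default 1; `α = 0` gives pure MLE and rejects
unseen parent configurations). With `α > 0` every assignment has positive
probability, which keeps bootstrap replicates and risk-arm evidence
consistent.

### Inference

Queries are answered by exact variable elimination (min-fill order, name
tie-break). A full-joint enumeration oracle (`brute_force_query`, guarded at
2^20 configurations) ships in the package; agreement to 1e-10 on random nets
is part of the test battery. When the evidence covers every non-target node
(subject scoring), the posterior reduces to a ratio of two full joint
products, computed vectorized — algebraically identical to elimination.
Zero-probability evidence raises an error rather than yielding NaN, because
silent NaNs would corrupt risk ratios downstream. Loopy belief propagation
was deliberately not implemented: the cohort nets are small, exactness is
testable, and an approximate engine would add unquantifiable error.

## Risk queries

The relative risk of outcome A given risk variables B, C, … is

    RR = P(A = flagged | B = flagged, C = flagged, ...)
       / P(A = flagged | B = complement, C = complement, ...),

with all unlisted variables marginalized, never conditioned. Both arms set
*all* listed variables simultaneously; this is a conditional-probability
ratio, not a causal effect (no adjustment sets, no do-calculus). Synergy is
read off by comparing a joint RR against its single-variable sub-scenarios;
note that CPT-level interaction and marginal-RR composition are different
quantities — marginal single-variable RRs already absorb part of an
interaction, so a supra-multiplicative CPT need not produce
`RR(B,C) > RR(B)·RR(C)` at the margin.

Uncertainty: percentile bootstrap. Rows are resampled with replacement to
the original N; structure AND parameters are relearned per replicate ("1000
nets", default `n_boot = 1000`); the 5th/95th percentiles of surviving
replicate RRs form a 90% interval. Replicates with an undefined RR are
discarded and counted, not imputed. Replicate index streams are derived per
replicate from `SeedSequence(seed, spawn_key=(r,))`, so extending `n_boot`
never changes earlier replicates, and a scenario battery shares one stream
across scenarios, making estimates comparable. Percentile intervals need not
bracket the full-data point estimate; both are reported without
reconciliation.

## Dichotomization

Fixed clinical rules, with comparators taken literally at the boundary:
MDI/PDI ≤ 70 low, LAZ ≤ −1.6 low (adverse); MDI/PDI > 100, LAZ > 0
(favorable); birthweight < 2500 g low; ventilation after stage-I palliation
> 7 d prolonged; gestational age < 37 wk preterm; census SES score < −0.3
low. Adverse-mode and favorable-mode discretizations are separate runs
producing separate cohorts — the forest-plot queries condition on binary
states, so a three-level encoding is never used. Missing data are handled
strictly by complete-case filtering; no imputation.

### Cutoff search

Where a cutoff is to be learned rather than fixed, `optimize_cutoff` runs a
grid search: dichotomize the target at each candidate, relearn structure and
parameters on the induced cohort (labels change the data, so a fixed
structure would leak an arbitrary choice), score each subject with
P(target flagged | all other observed variables), and take the cutoff with
the highest ROC AUC against the induced labels. Default grids use integer
steps for index scores and 0.1 steps for z-scores. Scoring uses the data the
net was fit on — the AUCs are optimistic and the procedure selects a cutoff,
it does not validate a classifier.

Degenerate candidates are excluded by `max(min_class_size,
ceil(min_class_share · n))` (defaults 5 and 0.05). The relative guard is
essential, not cosmetic: AUC values computed against severely imbalanced
label sets are not comparable across candidates — a handful of extreme-tail
subjects forms an artificially pure positive class whose AUC approaches 1,
and without the guard the argmax reliably ran to such degenerate cutoffs in
simulation. Ties in the argmax break toward the more balanced split, then
the smaller cutoff.

Known limitation (measured, not hypothetical): even with the guard, the AUC
argmax sits systematically a few points below the misclassification-optimal
cutoff when the flagged class is the minority, because a false positive
costs the AUC roughly `1/n_pos` while a false negative costs `1/n_neg`.
Under the default planted-cutoff simulation (below), the selected cutoff
lands in the 62–80 window with mean label agreement ≈ 0.985, while the
Bayes-optimal boundary would reach ≈ 0.992; users should treat the returned
cutoff as a starting point, not an estimate of a latent boundary.

## Group comparisons

Two-sided Mann–Whitney U (ties counted ½), exact enumeration when
`n1 · n2 ≤ 400` and the pooled sample is tie-free, else the normal
approximation with tie and continuity corrections; Bonferroni adjustment
takes the family size from the supplied p-value vector (the family is an
explicit analysis choice, never inferred). The identity
`AUC = U / (n1 · n2)` on the same data is checked to 1e-12 across modules.

## The synthetic cohort generator

Real single-ventricle cohort data are access-restricted, so all validation
runs on simulated cohorts with known ground truth. Presets:

- `svr_core` — 6 binary nodes. `dGV` (damaging variant, abnormal-heart-
  morphology gene list) has marginal prevalence **0.44** and `SYNDR`
  (damaging variant, syndromic-CHD gene list) **0.14** — the two published
  prevalence figures; `SEX_female` is an independent fair coin. CPTs (states
  `true`/`false`, rows lexicographic in sorted parents, first parent most
  significant):

  | node | parents | P(true) per row |
  |---|---|---|
  | dGV | — | 0.44 |
  | SYNDR | — | 0.14 |
  | SEX_female | — | 0.50 |
  | MDI_low | SYNDR, dGV | tt 0.94, tf 0.12, ft 0.20, ff 0.12 |
  | PDI_low | MDI_low | t 0.82, f 0.06 |
  | LAZ_low | SYNDR | t 0.84, f 0.12 |

  `dGV` alone raises outcome risk 0.12 → 0.20, `SYNDR` alone is neutral,
  both together reach 0.94 — a strongly supra-multiplicative (epistasis-like)
  interaction. The exact marginal RR for (MDI_low; dGV) under this truth is
  0.3036 / 0.12 ≈ **2.53**. Entry values other than the two published
  prevalences are design constants placed by a binomial power calculation:
  entries on low-count parent configurations (SYNDR-true rows, ~14% of
  subjects) are kept away from the high-variance middle of (0, 1) so the
  recovery checks below have ≥ 2.4 standard errors of margin at their stated
  sample sizes.
- `svr_clinical` — adds PRETERM (0.18), BWT_low | PRETERM (0.75/0.08),
  VENT_prolonged | BWT_low (0.60/0.25), SES_low (0.35).
- `chain_test` (A→B→C, effects 0.9/0.1), `collider_test` (A→C←B,
  P(C=t|A=B=t)=0.9 else 0.1), `independent_test` (three fair coins) — the
  small fixed nets used throughout the examples.

Sampling is ancestral with Philox counter-based streams; every sampling
purpose gets its own `spawn_key`, so adding draws never perturbs existing
ones and identical seeds give bit-identical tables. Continuous outcome
scores are emitted per latent state from Gaussian components (planted-cutoff
testing; default MDI-like emission N(60, 7²) for the flagged class, N(100,
10²) otherwise); the latent state is retained under `<target>__latent` for
recovery checks only and must be dropped before analysis. Emission standard
deviations are floored at 1e-6.

What the generator does NOT emulate: survival/enrollment bias, missing-not-
at-random patterns, anatomy/lesion covariates, continuous covariate
dependence beyond the binary truth net, and any attempt to match the real
cohort's full joint distribution. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
fidelity of any particular clinical estimate.

## Validation battery and problem sizes

The sizes below were chosen so the entire battery runs in minutes on one
CPU while leaving clear statistical margin; they are the same in the pytest
acceptance tests and in `scripts/acceptance.py`.

| check | size | expected outcome |
|---|---|---|
| structure search vs all-DAG oracle | 20 datasets, 4 nodes, N=200 | optimum attained 20/20 (tolerance 1e-9 for Markov-equivalence float ties) |
| variable elimination vs enumeration | 50 random nets ≤8 nodes | max abs deviation < 1e-10 |
| relative-risk identities | collider / independent presets | 9.0, 1.0, arm-swap inversion, all to 1e-12 |
| CPT recovery | svr_core, n=20,000 | every entry with expected cell count ≥100 within ±0.02 |
| chain Markov-class recovery | n=5,000, 20 seeds | ≥18/20 |
| planted-cutoff recovery | n=1,000, 20 seeds | see cutoff-search limitation above |
| bootstrap coverage | 100 cohorts n=500, n_boot=200 | truth RR inside the 5–95% interval in ≥80/100 |
| Mann–Whitney exactness | {1,2,3} vs {4,5,6} | U=0, exact two-sided p=0.1 |
| pipeline determinism | full run twice | byte-identical artifacts |

## Numerical and design notes

- Natural-log BIC with penalty `0.5 · ln(N)` per free parameter; larger is
  better.
- Log-likelihoods accumulate in log space from count tables; no
  intermediate products of probabilities.
- CPT rows are serialized in lexicographic parent-configuration order with
  parents sorted by name; JSON round trips are bit-exact on the written
  decimal representation.
- Missing-value tokens on input: empty string, `NA`, `NaN`
  (case-insensitive), configurable; cosmetic given complete-case semantics.
- The cohort loader makes no assumption about cohort size.
- All randomness in the package flows through explicit integer seeds; there
  is no global RNG state.
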