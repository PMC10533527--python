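# svbn — Bayesian-network risk analysis for clinical cohorts

`svbn` is a Python package for quantifying how binary genetic, demographic,
and clinical risk factors combine — individually and synergistically — to
change the probability of adverse outcomes in a patient cohort, using
discrete Bayesian networks. It was built around the analysis needs of
single-ventricle congenital heart disease studies, where neurodevelopmental
outcomes (Bayley MDI/PDI), linear growth (length-for-age z-score), damaging
genotype flags, and perioperative clinical variables are examined jointly,
but nothing in it is specific to that disease.

It is aimed at biostatisticians and clinical researchers who want
conditional-probability risk ratios with honest uncertainty, from exact
(non-heuristic) algorithms, on modest numbers of variables.

## What it computes

1. **Exact structure learning.** The BIC-optimal DAG over ≤20 discrete
   variables by dynamic programming over variable subsets:

       score(G) = Σ_v [ LL̂(v | pa(v)) − ½ ln(N) · k_v ]

   The result provably attains the global optimum under the parent cap —
   verified in the test suite against brute-force enumeration of all 543
   four-node DAGs.
2. **Exact inference.** Conditional queries P(target | evidence) by variable
   elimination, cross-checked against a full-joint enumeration oracle that
   ships with the package.
3. **Relative-risk queries with bootstrap CIs.** For outcome A and risk
   variables B, C, …:

       RR = P(A=flagged | B=flagged, C=flagged, …)
          / P(A=flagged | B=complement, C=complement, …)

   with unlisted variables marginalized. Confidence intervals are 5th/95th
   percentiles over networks relearned (structure *and* parameters) on
   bootstrap resamples (default 1000).
4. **Outcome dichotomization.** Fixed clinical threshold rules (e.g.
   MDI ≤ 70 low, ventilation > 7 d prolonged, birthweight < 2500 g low), plus
   a ROC-AUC grid search that selects a cutoff by relearning the network at
   each candidate.
5. **Group comparison.** Two-sided Mann–Whitney U (exact for small tie-free
   samples) with Bonferroni correction.
6. **Synthetic cohorts.** A generator with known ground-truth networks
   (published genotype prevalences 0.44 / 0.14, planted interactions,
   Gaussian score emissions) so the whole pipeline is testable without any
   restricted data.

## Worked example

```python
from svbn import (
    SyntheticSpec, build_preset_network, sample_discrete,
    learn_network, RiskScenario, relative_risk, bootstrap_ci,
)

truth = build_preset_network("svr_core")          # known ground truth
cohort = sample_discrete(SyntheticSpec(truth=truth, n_subjects=2000, seed=1))

net = learn_network(cohort)                        # exact BIC search + fit
print(sorted(net.structure.edges()))

scenario = RiskScenario("MDI_low", "true", (("dGV", "true"),))
print(round(relative_risk(truth, scenario), 3))    # truth-net RR
est = bootstrap_ci(cohort, scenario, n_boot=200, seed=7)
print(round(est.rr, 3), round(est.ci_lo, 3), round(est.ci_hi, 3))
```

Output:

```
[('MDI_low', 'PDI_low'), ('SYNDR', 'LAZ_low'), ('SYNDR', 'MDI_low'), ('dGV', 'MDI_low')]
2.53
2.372 2.031 2.755
```

The learned edges recover the generator's dependency skeleton (orientations
within a Markov equivalence class are not identifiable from data). The true
relative risk of a low MDI score given a damaging genetic variant under this
generator is 2.53; the network learned from 2,000 subjects estimates 2.37
with a 90% percentile-bootstrap interval of (2.03, 2.76), which covers the
truth.

The same analysis is available from the shell:

```bash
svbn simulate --preset svr_core --n 2000 --seed 1 --out cohort.tsv
svbn run --config pipeline.yaml        # simulate → discretize → learn → risk
svbn query --net net.json --target MDI_low --evidence dGV=true,SYNDR=true
```

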