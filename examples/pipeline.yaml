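# Full pipeline on a simulated cohort: simulate -> discretize -> learn -> risk.
# Run with:  svbn run --config examples/pipeline.yaml
seed: 7
out_dir: svbn_run
simulate:
  preset: svr_core
  n: 500
learner:
  max_parents: 3
  pseudocount: 1.0
scenarios:
  - label: dGV alone
    outcome: MDI_low
    risk_variables:
      - {variable: dGV}
  - label: SYNDR alone
    outcome: MDI_low
    risk_variables:
      - {variable: SYNDR}
  - label: dGV + SYNDR
    outcome: MDI_low
    risk_variables:
      - {variable: dGV}
      - {variable: SYNDR}
n_boot: 200
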