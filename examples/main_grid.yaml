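# Main comparison grid: 9 cells (n x AUC0), balanced 1:1 allocation,
# continuous normal markers, spike-averaged truths (AUC0 and AUC0 +/- 0.01).
# Run:  aucci simulate --config examples/main_grid.yaml \
#              --out-csv results/main.csv --out-json results/main.json
methods: [lt, mw, bamber, binormal, wilson, wilson_cc, agresti_coull,
          clopper_pearson, wald, wald_cc]
defaults:
  reps: 10000
  alpha: 0.05
  ratio: "1:1"
  perturb: true
  binormal_reps: 1000
scenarios:
  - {auc0: 0.7, n: 40,  seed: 101}
  - {auc0: 0.8, n: 40,  seed: 102}
  - {auc0: 0.9, n: 40,  seed: 103}
  - {auc0: 0.7, n: 100, seed: 104}
  - {auc0: 0.8, n: 100, seed: 105}
  - {auc0: 0.9, n: 100, seed: 106}
  - {auc0: 0.7, n: 200, seed: 107}
  - {auc0: 0.8, n: 200, seed: 108}
  - {auc0: 0.9, n: 200, seed: 109}
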