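# aucci — confidence intervals for the area under the ROC curve

In early-phase diagnostic and biomarker studies the area under the ROC curve
(AUC) summarises overall accuracy without committing to a threshold. Such
studies are typically small (n ≈ 40–200), use a case-control design, and
report large AUCs (0.7–0.9) — exactly the regime where many standard AUC
confidence intervals are either anti-conservative or cannot be computed at
all. `aucci` implements ten two-sided intervals for the AUC and the
Monte-Carlo machinery to compare them by coverage probability, interval
length and statistical power.

## The statistic and the intervals

For n₁ cases and n₀ controls (n = n₀ + n₁), the AUC is estimated by the
normalized Mann-Whitney statistic computed from pooled mid-ranks,

    AUĈ = (R̄₁ − R̄₀)/n + 1/2 ,

which equals P̂(X₁ > X₀) + ½·P̂(X₁ = X₀) over all case-control pairs and is
invariant under monotone transformations of the marker.

Because the AUC is a probability, single-proportion intervals apply with
"sample size" n. The centerpiece is a **modified Wald interval** that plugs
in Bamber's asymptotic *maximum* variance for continuous markers with
monotonic posterior,

    σ̂²max = AUĈ (1 − AUĈ) / (0.75·n − 1) ,
    AUĈ ± z₁₋α/₂ · σ̂max            (Wald)
    AUĈ ± [z₁₋α/₂ · σ̂max + 1/(2n)]  (Wald-cc)

— computable on a pocket calculator from a *published* AUC and total sample
size, no individual patient data needed. The continuity-corrected form
remains usable even at AUĈ = 1.

The nine comparators: the logit-transformed Mann-Whitney interval (LT, the
usual reference), the untransformed Mann-Whitney interval (M-W), Bamber's
interval (unbiased distribution-free variance), the binormal AUC interval
(Φ((x̄₁−x̄₀)/√(s₀²+s₁²)) with a delta-method SE), and the proportion family:
Wilson, Wilson with continuity correction, Agresti-Coull, Clopper-Pearson.
LT, M-W, Bamber and binormal require individual data; the rest work from
(AUĈ, n₀, n₁) alone.

## Worked example

A published study reports AUĈ = 0.86 with 51 controls and 90 cases. The six
summary-computable intervals:

```
$ aucci from-summary --auc 0.86 --n0 51 --n1 90
n0 (controls) = 51, n1 (cases) = 90, n = 141, AUC estimate = 0.860
Interval     Lower limit Upper limit    Length  Notes
Wilson             0.793       0.908     0.115
Wilson-cc          0.789       0.911     0.122
A-C                0.792       0.908     0.116
C-P                0.789       0.911     0.122
Wald               0.794       0.926     0.133
Wald-cc            0.790       0.930     0.140
```

All six agree to about ±0.01 on the lower limit; the Wald intervals are the
widest (they use the *maximum* variance), the Wilson interval the narrowest.
With individual data all ten become available:

```
$ aucci fixture --n0 51 --n1 90 --auc 0.86 --seed 2 --out study.csv
wrote study.csv: n0=51, n1=90, target AUC=0.860, realized AUC estimate=0.859
$ aucci estimate --data study.csv
n0 (controls) = 51, n1 (cases) = 90, n = 141, AUC estimate = 0.859
Interval     Lower limit Upper limit    Length  Notes
LT                 0.784       0.911     0.126
M-W                0.797       0.922     0.125
Bamber             0.797       0.921     0.124
Binormal           0.797       0.921     0.124
Wilson             0.792       0.907     0.115
Wilson-cc          0.788       0.910     0.122
A-C                0.791       0.907     0.117
C-P                0.789       0.911     0.122
Wald               0.792       0.926     0.133
Wald-cc            0.789       0.929     0.140
```

Simulation grids run from a YAML config (`aucci simulate --config grid.yaml
--out-csv results.csv --out-json summary.json`); see
`examples/main_grid.yaml` and `aucci.sim` for the library API
(`run_coverage`, `run_power`, `paper_grid`, `summarize_scenarios`).

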