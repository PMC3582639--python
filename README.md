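# cin4kit

Chromosomal instability (CIN) — the ongoing gain and loss of chromosomes in
tumor cells — is prognostic in breast cancer, but direct measurement
(centromere counting, flow-cytometric DNA index) is laborious. A practical
surrogate is a small gene-expression panel: reduce the 70-gene CIN
signature to its four most representative members (**AURKA, FOXM1, TOP2A,
TPX2** — the *CIN4* panel), measure them by qPCR together with three
stable reference genes (B4GALT3, SLC9A3R2, PUM1), and use the resulting
score to split the heterogeneous **grade 2** tumors into good- and
poor-prognosis groups.

`cin4kit` implements that entire workflow as a tested, reusable library
plus CLI, for statisticians and translational researchers who want to run
or stress-test the design on their own (or simulated) cohorts:

- **Signature reduction** — rank signature genes by Pearson correlation
  with the per-sample mean-signature score across multiple expression
  cohorts; take the top *k* (default 4).
- **qPCR scoring** — collapse duplicate wells with QC, then
  `score = mean(reference Ct) − mean(target Ct)`, a log2
  relative-expression (ΔCt) measure invariant to per-sample loading
  offsets. Undetermined wells are never imputed.
- **Nearest-shrunken-centroid classifier** (PAM-style), written from
  scratch: standardized centroid deviations
  `d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0))` with `m_k = √(1/n_k − 1/n)`,
  soft-thresholded by Δ, classification by
  `δ_k(x) = Σ_i (x_i − x̄'_ik)² / (s_i + s0)² − 2 log π_k`.
  Trained on the grade-1 vs grade-3 extremes using the continuous CIN4
  score, it yields a closed-form scalar threshold applied to grade-2 tumors.
- **Ploidy calling** — G1-peak detection in DNA-content histograms,
  DNA index = tumor-G1 / diploid-G1 channel, aneuploid iff DI > 1.10
  (strict).
- **Survival statistics** — Kaplan–Meier with Greenwood SE and restricted
  mean survival, log-rank, Cox proportional hazards (Newton–Raphson,
  Efron/Breslow ties) reporting HR with CI, LR/Wald/score tests,
  Harrell's concordance and Cox–Snell R² with its attainable maximum,
  plus a score-interaction model `hazard ~ a + b + a:b`.
- **Synthetic cohorts** — a seeded generator planting a latent CIN factor
  that drives expression loadings, Ct values, proportional-hazards
  recurrence, aneuploidy probability and clinical covariates, so every
  stage is testable against known truth without any external data.

## Worked example

```python
from cin4kit import SimConfig, run_study

report = run_study(SimConfig(seed=1))   # 185 tumors: 63 / 62 / 60 per grade
g2 = report.grade2_stratification
print(g2["n_low"], g2["n_high"], g2["logrank_p"], g2["hr_high_vs_low"])
```

which prints, formatted:

```
threshold          = 2.624  (delta* = 3.092)
grade-2 strata     : 34 low / 28 high
restricted mean RFS: low 75.1 +/- 7.3, high 49.3 +/- 8.5 months
log-rank           : chi2 = 5.68, p = 0.0171
Cox HR high vs low : 2.51 [1.15-5.46]
ploidy vs grade    : chi2 p = 0.0000
CIN4 vs DNA index  : slope = 0.087, p = 0.0000
```

Reading: the classifier threshold (2.624 on the ΔCt scale) learned from
grade extremes splits the 62 grade-2 tumors into 34 low- and 28 high-CIN4
cases; the high group relapses earlier (restricted mean recurrence-free
survival 49 vs 75 months, log-rank p = 0.017, hazard ratio 2.5), aneuploidy
is enriched in higher grades, and the CIN4 score rises with the DNA index —
the qualitative behavior the assay is designed to exhibit. Because the
planted hazard effect is moderate and a grade-2 stratum holds only 62
tumors, individual replicates vary; the calibration studies below quantify
that.

The same pipeline is scriptable from the shell:

```bash
cin4kit simulate --seed 1 --outdir sim/        # expression.tsv, qpcr.csv, clinical.csv, histograms/
cin4kit score --plate sim/qpcr.csv --out scores.csv
cin4kit run --seed 1 --out report.json
```

## Layout

| module | contents |
| --- | --- |
| `cin4kit.signature_reduction` | cohort container, mean-signature score, correlation ranking |
| `cin4kit.qpcr_scoring` | replicate collapse, QC, CIN4 ΔCt score, reference-gene stability |
| `cin4kit.nsc_classifier` | shrunken-centroid fit/classify, CV tuning, decision threshold |
| `cin4kit.ploidy_facs` | histogram peak detection, DNA index, diploid/aneuploid call |
| `cin4kit.survival_stats` | KM, log-rank, Cox (Efron/Breslow), interaction, χ², OLS trend |
| `cin4kit.synthetic_data` | seeded cohort generator with planted truth |
| `cin4kit.pipeline` | end-to-end study, immunophenotype rules, NPI |
| `cin4kit.io`, `cin4kit.cli` | plain-text formats, `cin4kit` command group |

See `docs/methods.md` for the statistical models, default parameters and
their rationale, numerical choices, and known limitations.
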