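# Methods

This note records the statistical models implemented in `cin4kit`, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data studies do and do not demonstrate.

## The CIN4 score

Chromosomal instability is proxied by the mean expression of a signature
gene set. On microarray-style data the per-sample score is the unweighted
mean of the signature genes' log2 expression. On qPCR data, where the
cycle threshold Ct falls by one cycle per two-fold expression increase,
the equivalent quantity is

    score = mean(Ct of reference genes) − mean(Ct of target genes),

i.e. mean target log2 expression minus mean reference log2 expression (a
ΔCt). Defining the score on the log2 scale rather than as `2^ΔCt` keeps it
linear in log-expression, which is what the downstream threshold
classifier consumes; any monotone transform would give the same risk
labels. The score is exactly invariant to a per-sample additive Ct offset
(template amount, global efficiency), which is the property that makes
relative quantification usable on archival FFPE material. PCR efficiency
is assumed 100% for all assays; no standard-curve correction is applied.

Replicate wells are collapsed by the mean of the determined replicates.
QC thresholds on the replicate spread (max − min): warn above 0.5 cycles,
fail above 1.0 cycles. These thresholds are this package's own convention;
typical instrument guidance treats half-cycle discordance as suspect.
Undetermined wells are never imputed (no "Ct = 40" substitution): a sample
missing any of the 4 target or 3 reference genes fails QC for the score
and is excluded with a flag naming the gene — conservative behavior for a
prognostic assay.

## Signature reduction

Each signature gene is correlated (Pearson) with the cohort's
mean-signature score, per cohort; a gene's rank statistic is the
unweighted mean of its per-cohort coefficients; ties break
lexicographically by gene id so the ranking is deterministic. Choices made
where the procedure was genuinely open:

- the gene under evaluation stays **inside** the mean score (no
  leave-one-out); a leave-one-out option exists but is off by default;
- cohorts contribute equally regardless of sample size;
- genes absent or constant in a cohort simply drop that cohort from their
  average rather than being imputed;
- matrices are used as provided (no per-gene standardization); an RMA-like
  log2 scale is assumed.

Grade correlations treat grade as numeric 1/2/3 (Pearson), with Spearman
available.

## Nearest-shrunken-centroid classifier

For feature *i* and class *k* with class centroid x̄_ik, overall centroid
x̄_i, pooled within-class SD s_i and fudge s0 (default: median of the
s_i):

    d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0)),   m_k = √(1/n_k − 1/n)
    d'_ik = sign(d_ik) · max(|d_ik| − Δ, 0)
    x̄'_ik = x̄_i + m_k (s_i + s0) d'_ik

The `1/n_k − 1/n` form of m_k is used because it is the exact variance
factor of x̄_ik − x̄_i when x̄_i includes class k's samples. Classification
minimizes δ_k(x) = Σ_i (x_i − x̄'_ik)²/(s_i + s0)² − 2 log π_k; posteriors
are proportional to exp(−δ_k/2). Exact δ ties break to the first class in
(sorted) label order. Priors default to observed class frequencies.

Δ is tuned by stratified cross-validation (default 10-fold, seeded,
refolded with a warning if a class is smaller than the fold count) on
misclassification error; among grid values attaining the minimum the
**largest** Δ is chosen (parsimony). The grid spans 0 to max|d_ik| of the
full fit.

For the grade-2 stratification the classifier is trained on the grade-1
vs grade-3 extremes with a **single feature**, the continuous CIN4 score;
the training step also supports the 4-gene feature vector, but the scalar
formulation is the default because it yields the interpretable expression
threshold that is the assay's deliverable. For a two-class, one-feature
model the decision boundary has the closed form

    x* = (a² − b² − 2 (s+s0)² log(π_a/π_b)) / (2 (a − b)),

the midpoint of the shrunken centroids under equal priors. With heavy
shrinkage and unequal priors x* can fall outside the centroid interval;
orientation therefore follows the sign of (a − b): scores above x* belong
to the class with the larger shrunken centroid.

## Ploidy from DNA-content histograms

Histograms are smoothed by a centered moving average (default 5 bins of a
1024-bin histogram, edge-padded so flat regions stay flat), local maxima
are kept if their prominence reaches 5% of the smoothed maximum, and
candidates within [1.90, 2.10]× an accepted G1 peak are tagged G2/M and
excluded from G1 candidacy. The lowest-channel G1 peak is taken as the
diploid reference (standard practice when no internal standard is
recorded); the tumor peak is the highest-prominence remaining G1 peak;
DNA index = tumor channel / reference channel, exactly 1.0 when only one
G1 peak exists. A tumor is called aneuploid iff DI > 1.10, strictly.

Known limitations, by construction: near-tetraploid tumors (true DI ≈
1.9–2.1) fall inside the G2/M exclusion window and are not evaluable;
hypo-diploidy is not modeled (a tumor peak below a user-supplied reference
is reported as reference/tumor with a `hypodiploid-ambiguous` flag); no
S-phase or debris deconvolution is attempted.

## Survival statistics

- **Kaplan–Meier**: product-limit estimator with Greenwood variance.
  "Mean RFS" is reported as the restricted mean survival time — the area
  under the KM curve up to a truncation time (default: largest observed
  time) — with the standard sum-over-event-times SE. With no censoring it
  reduces to the arithmetic mean of the truncated event times.
- **Log-rank**: observed-minus-expected over pooled event times with the
  hypergeometric variance including the finite-population factor
  (n_j − d_j)/(n_j − 1). Without tied event times this equals the Cox
  partial-likelihood score test exactly; with ties the classical variance
  carries the correction factor and the two differ slightly.
- **Cox regression**: Newton–Raphson on the partial likelihood to a score
  norm below 1e-8 (step-halving guards ascent; 50 iterations max), Efron
  tie handling by default — month-resolution times guarantee ties —
  with Breslow available for cross-checks against tools defaulting to it.
  Reported per model: coefficients, HR with Wald CIs on the log scale,
  likelihood-ratio / Wald / score statistics, Harrell's concordance,
  R² = 1 − exp(−LR/n) and its maximum 1 − exp(2·LL₀/n). |β| > 20 flags a
  monotone likelihood (separation).
- **Interaction test**: `hazard ~ a + b + a·b`, Wald test on the product
  term; rank-deficient designs are flagged, not raised.
- **Associations**: Pearson χ² without continuity correction (optional
  for 2×2), OLS slope t-tests, Welch t-tests for continuous-by-binary
  comparisons. No multiple-testing adjustment is applied; the reporting
  convention is a two-sided 0.05 level per test.

## The synthetic cohort generator

Each tumor carries a latent instability level L ~ Normal(μ_grade, σ) with
grade means (−1, 0, 1) and σ = 0.8. Grade is an input label, not a
function of L, so grade is a *noisy* proxy for instability — deliberately,
since training on grade extremes must contend with label noise, and some
high-score tumors should remain diploid. Defaults encode the motivating
study design: 63/62/60 tumors in grades 1/2/3, a 70-gene signature whose
first four members are the qPCR targets, duplicate wells for 4 target + 3
reference genes, and ~120 months of follow-up.

- **Expression**: signature gene g has loading λ_g ~ U(0.5, 1.5);
  expression = λ_g·L + N(0, 1). Background genes are independent N(0, 1).
  Planted-loading studies multiply the first k loadings by 3.
- **qPCR**: Ct = offset_g − expression + N(0, 0.25), duplicated with
  N(0, 0.15); gene offsets drawn once per cohort, U(22, 30). Reference
  genes carry no biological variation. An optional per-sample Ct offset
  (default off) emulates loading differences; the ΔCt score cancels it
  either way.
- **Survival**: event time ~ Exponential with hazard
  0.012·exp(log(2)·L) per month, censoring U(0, 120], times rounded to
  whole months (minimum 1) so ties occur as in clinical tables. The
  constant-hazard choice is the simplest mechanism satisfying
  proportional hazards, which is all the downstream tests require.
- **Ploidy**: P(aneuploid) = logistic(−0.1 + 1.0·L); aneuploid tumors get
  DI = clip(1.2 + 0.15·L + N(0, 0.12), 1.12, 1.85), diploid tumors
  DI = 1. Histograms are multinomial draws (20 000 events) from a
  Gaussian mixture: diploid G1 at channel 200 with G2/M at 400 (12% of
  its mass), tumor G1/G2 at DI×those positions for aneuploid tumors (35%
  of nuclei), 3% uniform debris, peak CV 1.2% of position.
- **Covariates**: Ki67, mitotic index, tumor size increase linearly in L
  with Gaussian noise; ER/PgR negativity and HER2 positivity have
  logistic dependence on L; age is L-independent. NPI is computed from
  size, nodal stage and grade by the standard 0.2·cm + stage + grade.

All sub-generators derive child seeds deterministically from the single
config seed; identical configs give bit-identical cohorts.

What the generator does **not** emulate: microarray probe effects and
normalization artifacts, tumor heterogeneity and subclonal structure,
FCS-level cytometry (debris/aggregate physics, S-phase), informative
censoring, multi-plate qPCR batch effects, or correlated noise between
genes. Passing tests therefore demonstrate the correctness and calibration
of the algorithms under the stated generative assumptions, not clinical
performance on real cohorts.

## Validation studies and problem sizes

The acceptance suite and `scripts/acceptance.py` run: classifier-vs-oracle
agreement on 1000 random instances (≤5 features, ≤20 samples); 2000
(suite) / 1000 (script) null simulations of the log-rank and 2000/500 of
the interaction test at n ≈ 60 per arm, expecting rejection within
[0.03, 0.07] at the 0.05 level; 50 replicate 500-tumor cohorts with a
planted per-unit hazard ratio of 2, expecting the mean estimate within
[1.9, 2.1] and CI coverage within [0.90, 0.98]; 100 replicate three-cohort
ranking studies with 4 genes at 3× loading, expecting top-4 recovery in
≥95%; DNA-index recovery within ±0.03 at DI ∈ {1.0, 1.05, 1.15, 1.3, 1.6}
(20 000 events); and 100 replicate end-to-end 185-tumor studies. In the
planted-loading study the base loadings are drawn from U(0.8, 1.2) so that
"3× the rest" is a genuine separation — under the default U(0.5, 1.5) a
boosted gene at the low edge coincides with an unboosted gene at the high
edge and recovery is limited by that overlap, not by the ranking method.

At the default effect size the grade-2 log-rank comparison (62 tumors,
~45% events) has power ≈ 0.4–0.45; the end-to-end study therefore asserts
the direction of the stratification (worse RFS in the high-CIN4 group in
the majority of replicates) and reports the rejection fraction rather than
asserting majority significance. A real 62-patient stratum is similarly
under-powered for moderate effects — the simulation is honest about it.
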