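# Methods

`apmeth` analyzes alternative promoter (AP) usage in paired tumor/normal
bulk RNA-seq and relates it to promoter CpG methylation. This note records
the models, the numerical choices, and what the synthetic benchmark does and
does not establish.

## Promoter catalog and activity

Transcripts are read from a Gencode-style GTF and grouped per gene by
strand-aware single-linkage clustering of first exons: transcripts whose
first exons overlap share a promoter. The grouping rule in the upstream
literature is stated only as "same or nearby TSS"; we use first-exon overlap
with no fixed bp window because the activity model requires promoters to map
to distinguishable splice-donor sites — two first exons that share a donor
boundary necessarily overlap, so within a gene every donor coordinate
belongs to exactly one promoter (asserted at runtime). Promoter ids are
regenerated deterministically (sorted by chromosome, TSS, gene), so ids from
other tools are treated as opaque labels. A promoter is flagged *internal*
when its first-exon cluster overlaps a non-first exon of a sibling
transcript; the flag marks promoters whose junction counts may absorb reads
from the overlapping transcript but does not change counting.

Raw activity of promoter *p* in sample *s* is the sum of column-7 unique
reads over junctions whose donor coordinate (0-based intron start on `+`,
half-open intron end on `-`) matches a donor site of *p*; multimapped reads
are excluded, and strand-undefined junctions (STAR code 0) are matched on
both strands. Counts are normalized with DESeq-style median-of-ratios size
factors (rows with any zero are excluded from the geometric means; if no
all-positive row exists we fall back to total-count ratios with a warning).
Absolute activity is `log2(count/sf + 1)`; the 0.25 minimum-activity
threshold used in AP calling is interpreted on this log2 scale. Relative
activity is a promoter's share of the summed absolute activity of its gene,
NA when the gene total is zero. Before normalization we drop promoters whose
member transcripts are all single-exon (no junction evidence can exist) and
promoters with zero counts in every sample.

## Differential analysis

Gene-level differential expression uses a two-sided paired t-test on
`log2(normalized + 1)` (pairs from the design table) with the conventional
decision rule p < 0.05 and |log2FC| > 1; the log2FC uses a pseudo-count of 1
on normalized group means. A negative-binomial GLM could be substituted
behind the same contract; the paired t on the log scale is robust, fast and
sufficient for the property-based guarantees tested here. Promoter-level
significance is a one-way ANOVA between tumor and normal on absolute and on
relative activity (for two groups this equals the equal-variance t-test,
F = t²; asserted to 1e-12 in tests). The promoter fold change is
`log2((mean_T + eps)/(mean_N + eps))` with eps = 0.001, the means taken on
the absolute (log2) activity scale — note this makes the 1.2-fold criterion
a ratio of log activities, which penalizes high-activity promoters more than
a count-scale ratio would. A promoter is a differentially regulated promoter
(DRP) when p < 0.05 and linear |FC| > 1.2. The 1.2 threshold is applied on
the linear scale (|log2FC| > log2 1.2). No multiple-testing correction is
applied by default, matching the raw-p conventions of this analysis style; a
`bh_correction` flag switches all gene/promoter p-values to
Benjamini–Hochberg adjusted ones.

## Alternative promoters

A promoter is an AP when all of the following hold: (1) its gene is
non-differential (gene p ≥ 0.05 and linear |FC| < 2); (2) mean absolute
activity exceeds 0.25 in both groups; (3) absolute and relative activity
both change significantly (p < 0.05); (4) absolute-activity linear |FC| >
1.2. The conjunction is evaluated as a single predicate with per-criterion
pass flags so filter attrition is auditable. Genes with both an up- and a
down-regulated AP are switch-usage genes. Isoform association classes follow
the most-significant (then largest-|FC|) member isoform, with ties broken by
larger |FC| then transcript id for determinism; the precedence
significant > fold-change-only is a documented interpretation where the two
overlap.

## Methylation integration

Betas are fractions in [0,1]; array matrices are joined to a manifest
(1-based positions converted to the internal 0-based convention), WGBS
ratios are read from bedGraph-like files with probes synthesized as
`chrom:pos`. Δβ = mean(tumor) − mean(normal), NAs excluded per group.
Distances to the TSS are signed in transcription direction (negative =
upstream). The representative CpG of a promoter is the CpG within ±1 kb of
the TSS (window endpoints inclusive) minimizing the Pearson-test p-value of
beta versus absolute activity across all samples, tumor and normal pooled
(a flag restricts to one condition); ties prefer smaller |distance| then
probe id. TSS methylation profiles use the deterministic 50-bp/25-bp-step
sliding-window mean across ±2 kb; quartile profiles split promoters by rank
of mean activity with ties broken by promoter id. Promoters whose
representative CpG correlation is significant (p < 0.05) are classed
negative or positive by the sign of r; mrAPs are APs with a negative class.
Group-level coupling is the Pearson correlation between Δβ and the activity
log2FC over promoters with |Δβ| > 0.1 (0.2 in strict mode). Cross-dataset
concordance confirms an activity change when at least one validation
tumor/normal pair shows a ≥1.2× linear ratio (activity back-transformed as
2^absolute − 1) in the reference direction, and a methylation change when
the same CpG (or, if uncovered, the ±1 kb region mean over CpGs covered in
all validation samples) shows a same-sign Δ > 0.1.

## Clinical models

The diagnostic model is an L1-penalized logistic regression of tumor status
on promoter activities. Features are standardized internally and
coefficients returned on the original scale. Lambda is chosen over a
100-point geometric path from the smallest all-zero lambda down to
lambda_max/100 when n < p (lambda_max/10⁴ otherwise — the glmnet
convention), at the minimum mean 10-fold cross-validated binomial deviance
with a fixed fold seed; ties prefer the sparser lambda, and a `lambda_rule=
"1se"` option applies the one-standard-error rule. The minimum-deviance rule
is known to overselect on small, strongly separable designs; tests therefore
assert that planted features are always kept and that held-out AUC is high
under the default rule, and assert sparsity under the 1-SE rule. The sample
score is the linear form Σ(activity × coefficient) without the intercept;
ROC/AUC are rank-based (Mann–Whitney, ties 0.5) and intercept-invariant.

Survival analysis dichotomizes a CpG's betas at the maximally selected
log-rank cutpoint: candidate thresholds are midpoints between sorted
distinct betas, both groups must hold at least `minprop = 0.1` of the
samples, the threshold maximizing |O−E|/√V is kept (ties → lower threshold).
Kaplan–Meier curves (via lifelines) and the log-rank chi-square p are
computed after administrative censoring at a 10-year horizon (times capped,
later events censored; clinical times are declared in years, or days
converted at 365.25). The reported p is the naive log-rank p at the chosen
cutpoint, with no correction for cutpoint selection — deliberately matching
the common usage of `surv_cutpoint`; a null-simulation test documents the
resulting type-I inflation rather than fixing it.

## Synthetic data generator

The generator defines the benchmark conditions: 200 genes, 19 tumor/normal
pairs, 1–3 promoters per gene with probabilities (0.43, 0.37, 0.20) (about
57% multi-promoter genes), per-promoter baseline mean junction count
lognormal(ln 15, 0.4) — moderate-depth bulk RNA-seq — negative-binomial
counts with dispersion 0.05, lognormal library factors (sd 0.2) and
per-gene pair effects (sd 0.25) that make the paired design informative.
Planted classes: DEG genes scale all promoters 4-fold; AP genes drop one
promoter's mean by 1/ap_fc (default 2) with the mass redistributed to
siblings so the gene total is constant; switch genes swap a 1.5×/0.5×
promoter pair. Because the fold-change criterion is a ratio of mean log2
activities under a constant gene total, a strong up-shift is only attainable
when a sibling drops sharply, so planted up-APs arise in switch genes — a
structural property of the AP definition, not a generator shortcut. Truth
tables label a planted promoter an AP only when its noiseless means satisfy
the fold-change criterion, so very high-baseline promoters whose log-scale
ratio cannot reach 1.2 are not counted against recall.

Methylation: 5 CpGs per promoter uniform in ±1 kb of the TSS; for AP
promoters selected as methylation-regulated (probability 0.6) one CpG is
coupled as `beta = invlogit(a0 − 1.5·z + N(0, 0.2))` where z is the
promoter's standardized log2 activity (standardization keeps the logit in a
responsive range; the raw log2 scale would saturate the inverse logit) and
a0 ~ N(0, 0.7); other CpGs are independent Beta(2,2); all betas clipped to
[0.01, 0.99]. The empirical per-CpG correlation is stored as `true_r`.
Survival: a separate 200-subject cohort with a latent binary risk group
drawn per subject that drives both prognostic-CpG betas (Beta(8,2) versus
Beta(2,8), so a median split recovers the group) and an exponential hazard
baseline ln2/4 per year times hazard_ratio^group (default 3); with
probability `censor_rate` (0.25) a subject is censored at a uniform fraction
of its event time. The genome layout, class assignment and effect sizes are
fixed by the design seed while counts/betas/survival use a separate data
seed, so replicate cohorts with identical planted truth can be drawn — used
to evaluate the diagnostic model held out.

What the generator does not emulate: overdispersed per-gene dispersion
trends, internal-promoter read leakage, array probe noise and detection
failures, spatially correlated CpG methylation, covariate-driven survival,
or batch structure. Passing the recovery tests shows the pipeline's logic
and statistics behave as designed under the stated model, not that the same
precision/recall would be obtained on real cohorts.

## Problem sizes and determinism

Tests and the acceptance script run the full study at 200 genes × 19 pairs
(≈350 promoters, 38 samples, ≈1 750 CpGs, 200-subject survival cohort),
averaged over 10 seeds for AP recovery and 5 for mrAP sensitivity; oracle
comparisons use exact brute force at n ≤ 30–60. All randomness flows from
explicit `numpy.random.default_rng` seeds; outputs are byte-reproducible
under a fixed seed (asserted in tests), and the LASSO uses a fixed
fold-assignment and solver seed.
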