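# Methods

## Study design the package models

The pipeline targets a two-cohort design common in relapsed-lymphoma
genomics: a small discovery cohort of matched primary/relapse tumor pairs
profiled by small-RNA sequencing with matched mRNA expression, and larger
independent survival cohorts in which candidate target genes are tested
as prognostic biomarkers. Identifiers (miRNA, transcript, gene) are
opaque case-sensitive strings throughout; transcript→gene mapping, if
needed, is the caller's concern and is applied only when summarizing
pairs.

## Normalization and paired differential expression

Counts are transformed to `log2((c + pseudocount) / libsize * 1e6)` with
library size the raw column sum and pseudocount 0.5 by default. The
paired test operates on per-patient differences (relapse − primary) of
the log2 values; log2FC is their mean. Two tests are offered:

- **paired t** (default): standard one-sample *t* on the differences.
  A miRNA whose differences have zero sample variance carries no usable
  information for the *t* statistic (even with a nonzero mean, the test is
  degenerate), so it is reported with p = 1 and a flag rather than an
  infinite statistic.
- **Wilcoxon signed-rank**: exact two-sided p by full sign-flip
  enumeration for n ≤ 25 informative pairs (zeros dropped, tied absolute
  differences given average ranks; the null distribution of the positive
  rank sum is built by dynamic programming over doubled ranks, which is
  exact for any tie pattern), normal approximation beyond.

Calls use the raw per-test significance level (default 0.05) with **no
multiplicity adjustment**; with hundreds of miRNAs this admits false
positives at the nominal rate, which is deliberate — the screen's error
control comes from the downstream anti-correlation and resource-support
filters, and the worked example makes the consequence visible (36 calls
from 13 planted effects at n = 300). Samples lacking their pair partner
are dropped from paired tests with a logged warning.

High/low classification against a reference matrix compares mean tumor
log2 expression with the mean reference expression; the offset thresholds
(default ±1 log2 unit) are **inclusive**, and a two-sided rank-sum
(Mann–Whitney) p < α is additionally required. When merging with DE
calls, DE status takes precedence, giving an exclusive and exhaustive
partition over {DE_up, DE_down, high, low, unclassified}.

## Anti-correlation target mining

Spearman ρ is the Pearson correlation of average ranks. Two-sided
p-values are exact (full enumeration of all n! rank permutations) for
n ≤ 8 and use the t approximation with n − 2 df otherwise; at the typical
pooled sample size (13–14) the approximation is adequate and is what the
pair miner uses. Zero-variance vectors have undefined ρ and are excluded.

Retention requires **strictly** ρ < −0.7 and p < 0.05 (both inequalities
strict; a pair at exactly −0.7 is excluded). Correlation is computed over
the pooled primary + relapse samples by default, configurable by
subsetting columns. Pair-level p-values are deliberately uncorrected for
multiplicity; support by at least `min_support` prediction resources
(default 1 of 5) is the error-control step, and each retained pair is
annotated with its exact supporting-resource set. Filtering is monotone:
tightening ρ, p, or support thresholds never adds pairs.

## Over-representation

One-sided hypergeometric tail P(X ≥ k) over a background universe that
defaults to the genes present in the expression data — the defensible
background for a query derived from that same data — with BH adjustment
across all tested sets. Gene sets are flat GMT; no GO-graph propagation.
Depletion is not tested.

## Survival

- **Kaplan–Meier**: product-limit estimator, right-continuous step
  function, S(0) = 1.
- **Log-rank**: 1-df chi-square from observed-minus-expected events with
  hypergeometric variance, summed over distinct event times (verified
  identical to lifelines).
- **Optimal cutpoint**: candidates are midpoints between consecutive
  distinct biomarker values whose split leaves both groups ≥
  `min_group_frac` (default 10%) of the cohort; the candidate with
  minimal log-rank p is selected ("high" = strictly above the cutoff).
  Ties on p are broken toward the larger chi-square, then the lower
  cutoff. The selected p is **not** corrected for the multiplicity of the
  scan; the full (candidate, p) profile is returned and exported so users
  can apply corrections. Users should be aware that minimum-p cutpoint
  estimates are noisy: in simulations at n = 233 with a hazard ratio of 4
  at the 75th percentile, the selected cutpoint is unbiased but has a
  sampling SD of ≈ 3.5 percentiles, so individual runs commonly land
  several percentiles from the true change point.
- **Cox model**: partial-likelihood maximization by Newton iterations
  with step-halving; Efron tie handling by default, Breslow available.
  Categorical covariates are dummy-coded against their first level
  (pandas Categorical order is respected, e.g. IPI 0–2 as reference for
  the 3–5 stratum). RR = exp(β) with Wald 95% CI and p per term.
  Non-convergence, singular information and likely separation
  (|β| > 15) are flagged on the result, never silent. Agreement with R's
  `survival::coxph` on tied fixtures is 1e-6 or better for both tie
  methods.
- **Cohort summaries**: per-category counts with percentages rounded to
  integers for display and a χ² association test (no continuity
  correction) across groups; a single-category characteristic has an
  undefined association p (NaN). The bundled CGCI/LLMPP characteristic
  tables are reconstructed from published per-subtype marginal counts
  (each characteristic filled independently within subtype, NA for
  missing data); one printed total in the source (CGCI IMPA1 "High") is
  inconsistent with its own subtype cells, and the self-consistent
  subtype cells are used.

Times are months; overall survival runs from diagnosis to death from any
cause or last follow-up, progression-free survival from diagnosis to
progression or death from any cause, so death counts as an event under
both endpoints.

## qRT-PCR quantification

Replicates are averaged **on the Ct scale** before ΔCt (the conventional
reading of the 2^−ΔΔCt method), with replicate SD kept for QC (flag above
0.5 Ct by default; a single replicate is unassessable). Amplification
efficiency is fixed at 2; no efficiency correction. ΔCt = target −
control per specimen, ΔΔCt = ΔCt(sample) − ΔCt(calibrator), rq = 2^−ΔΔCt
exactly, so swapping sample and calibrator inverts rq to machine
precision. In paired summaries, patients with undetected (zero or
missing) quantities in either phase are excluded with a logged note
rather than imputed.

## Synthetic-data generator

The generator produces every pipeline input with known planted truth.

- **miRNA counts**: negative binomial with variance m + φm² (default
  dispersion φ = 0.1), relative abundances log-normal (σ = 1.5), mean
  library size = requested depth (default 10⁶, a scaled-down stand-in for
  ~30 M-read libraries), and a **unit-mean log-normal per-patient
  baseline** (σ = 0.5 natural-log units) shared by the primary/relapse
  pair — this within-patient correlation is what a paired test exploits,
  and without it the generator would unrealistically favor unpaired
  analyses. DE miRNAs multiply the relapse mean by 2^±effect (default
  effect 2 log2 units, random sign); default design is 7 pairs with
  round(500 × 0.026) = 13 planted DE miRNAs.
- **mRNA**: generated directly on the log2 scale (the integration stage
  consumes normalized expression, so count-level realism adds nothing);
  planted targets follow baseline + strength × (centered regulator log2)
  + N(0, noise_sd), defaults strength −1.5, noise 0.2; all other genes
  are independent of every miRNA.
- **Resources**: each of 5 resources includes each true edge with
  probability `sensitivity` (default 0.8) and each false edge with a
  small `fp_rate`, independently per resource.
- **Gene sets**: 50 sets of 20–80 genes; one planted set draws 70% of its
  members from the true target genes.
- **Survival**: exponential event times with baseline hazard ln2/36 per
  month (36-month median, a realistic aggressive-lymphoma scale), hazard
  multiplied by the planted ratio above the true cutpoint and by optional
  categorical-covariate ratios; censoring is an independent exponential
  race tuned so each subject is censored with exactly the requested
  probability (default 0.3 in the recovery suites).
- **Ct tables**: target Ct = control Ct + calibrator ΔCt (default 2) −
  log2(true rq) + N(0, noise_sd) per replicate, 3 replicates by default.

Same seed + parameters ⇒ bit-identical output; pipelines derive
per-component sub-seeds from one global seed via `component_seed`
(SeedSequence mixing, stable under addition of new components).

What the generator does **not** emulate: read-level sequencing artifacts,
isomiRs, GC/length biases, batch effects, correlated decoy genes
(co-expression modules), non-proportional hazards, and informative
censoring. Recovery tests passing on this generator therefore demonstrate
correctness of the estimators under the stated models, not robustness to
those real-data complications.

## Problem sizes and numerical choices

The bundled test and reproduction runs use scaled-down but
design-faithful sizes chosen to keep full runs fast on a laptop: 120–500
miRNAs, 7 pairs, 400–1500 genes, 5 resources, 50 gene sets, survival
cohorts of 92 and 233 (the validation-cohort scales), 100-run cutpoint
recovery and 200-simulation Cox calibration. Newton iterations stop at
gradient ∞-norm < 1e-9 or likelihood change < 1e-12 (max 50 iterations
with step-halving). Exact enumeration limits: n ≤ 8 for Spearman
permutations, n ≤ 25 informative pairs for signed-rank sign-flips. Ties
use average ranks everywhere; threshold closures are inclusive for
high/low classification and strict for the anti-correlation filter, as
stated above.

## Known limitations

- The pair miner is O(miRNAs × genes) dense correlation; at genome scale
  (tens of thousands of genes × hundreds of miRNAs) memory for the rank
  matrix product is the limit, and chunking by miRNA subset is advised.
- The optimal-cutpoint p-value is biased low by the scan's multiplicity
  (by design, mirroring common practice); downstream users should treat
  it as a selection statistic, not a confirmatory p.
- The Cox implementation targets small categorical models (a handful of
  terms); it has no penalization, stratification, or time-varying
  effects.
- The high/low classifier assumes the reference matrix is on the same
  log2 scale as the normalized tumor data; no cross-platform calibration
  is attempted.
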