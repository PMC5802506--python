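# mirelapse

Integration analysis of matched primary/relapse tumor miRNA and mRNA
expression profiles, built for the paired study design used in relapsed
diffuse large B-cell lymphoma (DLBCL): a small discovery cohort of
patients with a tumor sample at diagnosis and a second sample at relapse,
matched mRNA profiles, external miRNA target predictions, gene-set
annotations, and independent survival cohorts for validating candidate
target genes.

It is aimed at computational biologists analyzing small-RNA sequencing of
paired tumor specimens who want a tested, scriptable alternative to
ad-hoc notebook analyses for this workflow.

## What it computes

1. **Paired differential expression.** Counts are normalized to
   log2 counts-per-million, and each miRNA is tested for
   relapse-vs-primary change within patients (paired *t* by default, exact
   Wilcoxon signed-rank as an option); log2FC is the mean over patients of
   (relapse − primary). miRNAs are additionally classed *high*/*low*
   against a non-malignant reference matrix by mean offset plus rank-sum
   test.
2. **Anti-correlation target mining.** Because miRNAs mostly repress
   their targets, candidate regulatory pairs are mined as
   (miRNA, gene) combinations with Spearman ρ < −0.7 and *p* < 0.05
   across the pooled tumor samples, then filtered for support by at least
   one of *k* target-prediction resources (TargetScan/PITA/miRTarBase-style
   edge sets).
3. **Over-representation.** Target-gene lists are tested against GMT
   gene-set collections with the hypergeometric tail
   P(X ≥ k), X ~ Hypergeom(N, K, n), and Benjamini–Hochberg correction.
4. **Survival.** Continuous biomarkers are dichotomized at the most
   prognostic cutoff (minimum log-rank *p* over all admissible splits),
   with Kaplan–Meier curves and a Cox proportional-hazards model
   (Newton-maximized partial likelihood, Efron or Breslow ties) reporting
   RR = exp(β) with Wald 95% CIs; cohort characteristic tables are
   summarized with χ² association tests.
5. **qRT-PCR.** Replicate Ct tables are aggregated on the Ct scale and
   converted to relative quantities by the 2^−ΔΔCt method, with paired
   log2-ratio summaries per miRNA.

Every input can also be *simulated* with planted ground truth
(`mirelapse.synthetic`), so each stage has a parameter-recovery test: a
negative-binomial paired count model with shared per-patient baselines,
planted repressive miRNA→gene maps, partially overlapping prediction
resources, one planted enriched pathway, proportional-hazards survival
cohorts, and noisy Ct replicates.

## Worked example

A fully synthetic end-to-end run (300 miRNAs, 7 patient pairs, 1500 genes,
5 prediction resources, a 233-patient survival cohort with a planted
hazard ratio of 4 above the 75th biomarker percentile):

```bash
mirelapse run-all --simulate --seed 7 --out demo_run
```

prints

```
report written to demo_run/run_report.yaml
  inputs: {'n_mirnas': 300, 'n_samples': 14}
  expression: {'n_de': 36, 'n_de_up': 22, 'n_de_down': 14, 'n_high': 23, 'n_low': 45}
  integration: {'n_candidate_pairs': 1724, 'n_supported_pairs': 392, 'n_unique_genes': 390, 'recall_vs_truth': 1.0, 'precision_vs_truth': 0.9948979591836735}
  enrichment: {'n_sets_tested': 50, 'top_set': 'PLANTED_PATHWAY', 'top_adjusted_p': 1.25947800729533e-21}
  survival: {'cutpoint': 0.8755853838515961, 'logrank_p': 4.205905702452427e-12, 'n_low': 193, 'n_high': 40, 'cox_terms': ['expression_group_high', 'IPI_3-5'], 'cox_rr': [4.232123948330159, 1.4890379129568319], 'cox_converged': True}
```

Reading the report: 36 miRNAs are called differentially expressed at raw
p < 0.05 (the 13 planted effects plus chance calls at that unadjusted
level); 1724 anti-correlated candidate pairs collapse to 392 after the
resource-support filter, recovering all 390 planted regulatory edges with
99.5% precision; the planted pathway ranks first in the enrichment; and
the survival stage dichotomizes the biomarker near the planted 75th
percentile and estimates RR ≈ 4.2 for the high-expression group (truth 4)
with the IPI covariate in the model. All intermediate tables (status,
pair, enrichment, KM, Cox, profile) are written as TSV next to the
report, and `inputs/truth.txt` holds the planted truth.

The same stages are available as `mirelapse de`, `classify`, `integrate`,
`enrich`, `survival` and `qpcr` subcommands over user-supplied TSV/GMT
files, and as plain library calls.

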