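# cnvburden

Rare copy-number-variant (CNV) gene-set burden analysis for case-control
cohorts with sleep-related phenotypes.

Large genomic deletions (DEL) and duplications (DUP) that remove or add a
copy of coding genes are a major source of liability for neurodevelopmental
conditions such as autism. A recurring question is whether CNVs hitting a
*specific* gene set — here, circadian-pathway genes and insomnia-risk genes
from GWAS ("sleep-risk genes") — carry more risk than CNVs hitting other
coding genes, and whether they also move sleep phenotypes (sleep duration,
insomnia traits). This package implements the full analysis as a tested,
reusable library:

* **Rare-CNV filtering** — keep autosomal calls ≥ 50 kb with ≥ 10 probes,
  < 50% overlap with masked regions (segmental duplications, centromeres,
  HLA), frequency < 1/1000 in a population panel at 70% reciprocal overlap,
  and < 50% covered by panel regions above 1% frequency. A sensitivity
  filter removes known recurrent neuropsychiatric CNVs (16p11.2-like loci).
* **Dosage burden scoring** — per individual and per cell of
  {DEL, DUP} × {sleep genes, other genes}: gene counts, Σ 1/LOEUF
  (intolerance to haploinsufficiency; low LOEUF = intolerant), and Σ DS
  (differential-stability brain-expression score in [0, 1]).
* **Burden regressions** —

      Model 1:  logit(case) ~ β0 + β1·DEL(Σ sleep genes) + β2·DUP(Σ sleep genes)
                             + β3·DEL(Σ other genes)  + β4·DUP(Σ other genes)
      Model 2:  the same with Σ 1/LOEUF (or Σ DS) in place of gene counts
      Model 3:  sleep duration (minutes) ~ the same four burden terms (OLS)
      Model 4:  insomnia traits (0–2)    ~ the same terms (proportional odds)

  with optional covariates (age, sex, cognitive z), family clustering
  (cluster-robust, GEE exchangeable, or variational random intercept), a
  weakly-informative-prior mode for sparse carrier counts, and a Bonferroni
  gate at p < 0.05/3 ≈ 0.017 for the three burden weightings.
* **Resampling** — percentile bootstrap 95% CIs over individuals
  (stratified by case status) to ask whether sleep-gene terms are
  *distinctly* stronger than other-gene terms, and a matched random-CNV
  null that replaces each case CNV with a genome-wide CNV of equal gene
  count and Σ1/LOEUF bin to test target-set enrichment.
* **Synthetic cohorts** — a first-class generator that plants known
  logistic / linear / proportional-odds coefficients so every stage can be
  validated by parameter recovery.

## Worked example

`examples/03_burden_models.py` simulates 8000 individuals where each
sleep-gene deletion raises the log-odds of case status by 0.5, then fits
the burden models:

```
Model 1 (logistic, gene counts; planted DEL_target log-OR = 0.5):
      term    beta     se     or  ci_low  ci_high      p  significant
 intercept -0.0211 0.0299 0.9791 -0.0798   0.0375 0.4801        False
DEL_target  0.5671 0.0757 1.7631  0.4187   0.7155 0.0000         True
DUP_target  0.0189 0.0724 1.0191 -0.1230   0.1609 0.7939        False
 DEL_other  0.0015 0.0099 1.0015 -0.0179   0.0209 0.8793        False
 DUP_other  0.0023 0.0102 1.0023 -0.0176   0.0223 0.8182        False

Model 3 DEL_target slope (min/gene, null): -2.47
Model 4 DEL_target cumulative OR (null): 0.99
```

The planted deletion effect is recovered (0.567 ± 0.076 against a true
0.5, OR ≈ 1.76 per sleep gene deleted) and survives the Bonferroni gate;
the unplanted terms and the null sleep-phenotype models sit at zero. The
other examples cover simulation (`01`), filtering and scoring (`02`),
bootstrap/matched-null sensitivity analyses (`04`), and carrier
descriptives (`05`).

A thin CLI mirrors the library (`cnvburden simulate | filter | annotate |
fit | bootstrap | report | run-all`); `run-all` executes the whole
pipeline from one YAML config and writes a reproducibility manifest.

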