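# Methods

## Coordinates and interval conventions

All intervals are 0-based half-open (`[start, end)`), the BED convention;
a reader flag converts 1-based inclusive (PennCNV-style) tables on input.
Chromosome names can be normalized by stripping or adding a `chr` prefix.
"70% overlap" between a CNV and a frequency-panel entry is interpreted as
*reciprocal* overlap — `min(overlap/len(a), overlap/len(b)) >= 0.7` — the
standard CNV-matching convention, because it prevents a small call inside
a large polymorphic region (or vice versa) from counting as a match. A
one-way (query-only) mode is available (`FilterParams.overlap_mode`)
since conventions differ across pipelines. Coverage fractions are always
computed against the *union* of regions so overlapping panel or mask
entries are not double-counted.

## Rare-CNV selection

A call survives filtering iff it is ≥ `min_size_bp` (50 kb), supported by
≥ `min_probes` (10), covered ≤ `max_mask_fraction` (0.5) by the union of
masked regions (segmental duplications, centromeres, HLA — pooled, since
they act as one reliability mask), autosomal (sex-linked dosage is not
comparable), and rare: (a) no same-dosage panel entry with frequency ≥
1/1000 matches at ≥ 70% reciprocal overlap, and (b) under 50% of the call
is covered by same-dosage panel regions above 1% frequency. Panel
matching is dosage-specific by default (population frequencies differ
between deletions and duplications, and all scoring downstream is
dosage-stratified); a pooling switch exists. Rules are evaluated in a
fixed order (size → probes → mask → autosome → rare-a → rare-b) and each
exclusion is attributed to the first failing rule, which makes the
exclusion tally deterministic and order-independent. Filtering is
monotone: loosening any threshold can only add survivors.

The recurrent-CNV exclusion (default ≥ 0.4 reciprocal overlap with a
known hotspot list) is a sensitivity filter, not part of the core
definition of "rare".

## Gene annotation and burden scores

A gene belongs to a CNV under the default `contained` rule iff its full
span lies inside the call ("genes encompassed"); an `any_overlap` rule is
offered because partial-overlap handling is a genuine convention choice
and neither option is asserted as canonical. Per CNV, gene content is
partitioned into a *target* set (circadian, insomnia, or their union) and
all *other* coding genes; a gene in both single sets counts once under
the union. Three metrics accumulate per side: gene count, Σ 1/LOEUF, and
Σ DS. Genes with a missing LOEUF or DS still count toward gene numbers
but cannot contribute to the corresponding weighted sum; a warning is
logged. Gene-set membership in file inputs is resolved by exact
uppercased symbol match — alias resolution is out of scope and should be
done upstream.

Per-individual profiles are the cellwise sums over all surviving CNVs:
12 numbers per person ({DEL, DUP} × {target, other} × 3 metrics), with
explicit all-zero rows for non-carriers, because burden regressions need
the non-carrier mass.

## Regression models

All four models share the same four burden predictors, selected by a
weighting (count, `inv_loeuf`, `ds`) and a target set.

* **Case-control (Models 1–2).** Logistic regression. The default
  `flat` prior mode is plain maximum likelihood (Newton, tolerance 1e-10),
  which admits closed-form checks: on a single binary predictor the
  coefficient is exactly the 2×2 log odds ratio. Rare-CNV designs
  produce sparse carrier cells and occasionally complete separation; the
  `weakly_informative` mode computes a MAP estimate under independent
  Student-t(df 3, scale 2.5) priors on standardized coefficients
  (scale 10 for the intercept), the common weakly-informative default for
  GLMs. Standard errors come from the inverse curvature of the penalized
  likelihood at the mode, delta-transformed back to the original scale.
  Flat-prior fits that fail or diverge raise `SeparationError` with the
  advice to switch priors rather than silently returning ±∞.
* **Family clustering.** `cluster_method="robust"` leaves point
  estimates untouched and sandwiches the covariance by family;
  `"gee_exchangeable"` fits a GEE with exchangeable working correlation;
  both reduce exactly to the independent fit when every family has one
  member (tested). `"random_intercept"` fits a variational Bayes
  random-intercept logistic model; it is approximate and offered for
  sensitivity, not as the reference fit.
* **Sleep duration (Model 3).** OLS in raw minutes; an optional z-scored
  outcome mode divides by the outcome SD for effect sizes comparable
  across cohorts.
* **Insomnia traits (Model 4).** Proportional-odds cumulative-logit
  model with two thresholds and shared slopes, fit by maximum likelihood
  (BFGS). The trait score is the count of endorsed items (difficulty
  falling asleep; frequent/prolonged awakenings) and is defined only when
  both items are answered; incomplete responses are missing, never
  imputed. With no predictors, the thresholds have the closed form
  `logit(cumulative frequency)`, which is used directly (it is the MLE)
  and as a test oracle. Thresholds are reported on the cumulative
  log-odds scale; the second threshold's SE uses the delta method over
  the fitter's internal increment parameterization. Family clustering is
  not implemented for the ordinal model; requesting it warns and fits
  independently.
* **Multiple comparisons.** The Bonferroni gate defaults to
  α/3 ≈ 0.017, correcting for the three burden weightings tested per
  model family; `n_tests` is configurable.

Wald 95% intervals throughout; odds ratios are `exp(beta)`.

## Resampling

* **Bootstrap.** Individuals are resampled with replacement, stratified
  by case status when the outcome is binary (each replicate keeps the
  observed case/control split), the model is refit, and percentile 2.5/97.5
  bounds are reported per term. Percentile rather than BCa intervals:
  the quantity of interest is a CI *comparison* (do the sleep-gene and
  other-gene intervals overlap?), for which the simple percentile
  interval is adequate and transparent. Replicates that fail to refit
  (separation) are skipped and counted; more than 10% failures raises a
  diagnostic error instead of reporting a quietly biased interval.
  Interval comparison treats intervals as closed: touching endpoints
  overlap.
* **Matched random-CNV null.** Each case CNV is replaced by a pool CNV
  matched on total gene count (± `gene_count_tolerance`) and on Σ1/LOEUF
  quantile bin (default deciles of the pool; exact matching on a
  continuous score is measure-zero). Sampling is with replacement per
  case CNV by default (a without-replacement mode exists and falls back
  to reuse when a candidate list is exhausted rather than aborting a
  resample). The statistic is the total target-set gene count (or
  Σ1/LOEUF) of the replacement set, and the empirical p uses the add-one
  rule `(1 + #{null ≥ observed}) / (1 + n)`, which is never exactly zero.
  CNVs with no admissible match abort with a diagnostic listing rather
  than being silently dropped, since dropping the hardest-to-match (large,
  intolerant) CNVs would bias the null toward significance.

## Synthetic cohorts

The generator emulates the study design at roughly 1/16 scale so the
full pipeline runs in seconds: 22 autosomes of 12 Mb with 1200
non-overlapping genes, a 20-gene circadian set and a 66-gene insomnia
set overlapping by 2 (mirroring the real ~312 and ~1053 gene lists out
of ~19k coding genes, with minimal overlap), and a 12-gene ASD-risk set.
LOEUF is a lognormal clipped to (0, 2] (gnomAD-like), with sleep genes
multiplied by 0.7 before clipping so their distribution skews toward
intolerance; DS is Beta(2, 3) for background genes and Beta(2.8, 2.2)
for sleep genes (higher brain-expression stability). All shapes are
configurable.

Per individual, CNV counts are Poisson (`cnv_rate`, default 0.4 per
person, giving overall carrier fractions broadly in the range the large
cohorts report), sizes log-uniform on [50 kb, 1.5 Mb], placement uniform
over autosome bases, rejecting mask overlaps by default so that
generated data passes the filter stack (a contamination fraction can
inject sub-threshold calls to exercise the filters). Probe counts are
length/5 kb with a floor of 10. Deletion share defaults to 0.4.

Phenotypes are sampled *after* burden features, from exactly the model
families the package fits: case status from a logistic model on the four
burden terms (intercept defaults to `logit(n_cases/n_total)`, so the
realized case split is stochastic around the requested one — this is a
retrospective labeling design, matching the likelihood being fit, not a
case-control sampling scheme); sleep duration from a linear model with
intercept 660 min and residual SD 76 min (matching a mean of ~11 h in
school-age cohorts and the reported −19 min ≈ −0.25 z conversion);
insomnia traits from a proportional-odds model with thresholds
logit(0.61) = 0.447 and logit(0.90) = 2.197, reproducing base rates of
39% for ≥ 1 trait and 10% for both traits. The two report items are
derived consistently from the trait count and independently masked as
missing (default 5%) to exercise the completed-responses rule. Families
are modeled as blocks of `family_size` sharing a lognormal CNV-rate
multiplier, which induces the within-family correlation the clustered
fits are meant to absorb.

All randomness flows through one `numpy.random.default_rng` (PCG64);
a fixed config seed reproduces every output byte-for-byte.

What the generator does **not** emulate: linkage disequilibrium,
ancestry structure, array-platform noise, recurrent-CNV hotspot
mutation mechanisms (hotspot regions exist only as fixed stand-in
coordinates), gene-density covariation with CNV occurrence (placement
is uniform by default), and realistic phenotype-covariate correlations
(age, sex, and cognitive z are independent draws unless slopes are
planted). Passing recovery tests therefore validates the *estimators
and plumbing* under the assumed generative models, not robustness to
real-data artifacts.

## Problem sizes used in checks

Parameter-recovery runs use cohorts of 10k–20k individuals with CNV
rates of 2–4 per person — higher than the descriptive defaults — so
that the planted coefficients' standard errors (≈ 0.04 for the Model 1
log-OR, ≈ 1.4 min for Model 3, ≈ 0.01 for Model 4) are comfortably
inside the recovery tolerances; these are power choices for the checks,
not claims about realistic carrier rates. Null calibration uses 200
cohorts of 500; enrichment detection uses 50 replicates of 40 case CNVs
against a pool from a 1200-person cohort.

## Known limitations

* The published carrier table is bundled for arithmetic cross-checks
  only; a handful of its printed percentages are internally inconsistent
  with their own counts under any single rounding rule, and those cells
  are flagged (`consistent=False`) and excluded from exact checks.
* "Bayesian logistic regression" is implemented as a MAP fit, not
  posterior sampling; reported intervals are Wald/curvature intervals.
* Transcript-level annotation, alias resolution, liftover, and raw CNV
  calling are out of scope; inputs are expected as harmonized calls.
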