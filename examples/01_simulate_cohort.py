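"""Simulate a case-control cohort with a planted deletion burden effect.

Builds a scaled autosomal genome with circadian and insomnia gene sets,
then generates CNV calls and phenotypes where deletions hitting sleep
genes raise the log-odds of being a case by 0.8 per gene.
"""

import cnvburden as cb

genome = cb.simulate_genome(seed=0)
n_sleep = sum(1 for g in genome.genes if g.sets & {"circadian", "insomnia"})
print(f"genome: {len(genome.genes)} genes on {len(genome.chromosomes)} autosomes, "
      f"{n_sleep} sleep-risk genes")

config = cb.SimulationConfig(
    n_cases=1000, n_controls=1000, cnv_rate=1.0,
    planted_betas={"DEL_target": 0.8},
    seed=1,
)
calls, phenotypes = cb.simulate_cohort(genome, config)
carriers = phenotypes["sample_id"].isin({c.sample_id for c in calls}).mean()
print(f"cohort: {len(phenotypes)} individuals, {len(calls)} CNV calls, "
      f"{100 * carriers:.1f}% carry at least one CNV")
print(f"realized case fraction: {phenotypes['case_status'].mean():.3f}")
print("Carrier rates and the case split are stochastic around the configured "
      "Poisson rate and the planted logistic model.")
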