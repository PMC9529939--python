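"""Published cohort descriptives used as arithmetic cross-checks.

Carrier counts of circadian- and insomnia-gene CNVs reported for four
large cohorts (a pooled general population, two ASD proband cohorts, and
unaffected siblings), together with the genome-wide CNV event counts per
gene set. These printed counts are inputs: the package recomputes the
percentages and totals from them, it does not assert them.

Cells whose printed percentage is consistent with round-half-up of
100*k/N to two decimals carry ``consistent=True``; a few published cells
were rounded differently (or are internally inconsistent) and are kept
here for completeness but excluded from exact checks.
"""

from __future__ import annotations

import pandas as pd

COHORT_SIZES = {
    "general_population": 7509,
    "ssc_probands": 2571,
    "mssng_probands": 3289,
    "ssc_siblings": 2092,
}

# (cohort, gene_set, side, dosage) -> (n_carriers, printed_percent)
_CELLS = [
    ("general_population", "circadian", "target", "DUP", 72, 0.96),
    ("general_population", "circadian", "other", "DUP", 1276, 16.99),
    ("general_population", "circadian", "target", "DEL", 12, 0.16),
    ("general_population", "circadian", "other", "DEL", 669, 9.30),
    ("general_population", "insomnia", "target", "DUP", 136, 1.81),
    ("general_population", "insomnia", "other", "DUP", 1240, 16.51),
    ("general_population", "insomnia", "target", "DEL", 85, 1.13),
    ("general_population", "insomnia", "other", "DEL", 610, 8.12),
    ("ssc_probands", "circadian", "target", "DUP", 72, 2.80),
    ("ssc_probands", "circadian", "other", "DUP", 702, 27.30),
    ("ssc_probands", "circadian", "target", "DEL", 31, 1.20),
    ("ssc_probands", "circadian", "other", "DEL", 348, 13.53),
    ("ssc_probands", "insomnia", "target", "DUP", 99, 3.85),
    ("ssc_probands", "insomnia", "other", "DUP", 687, 26.72),
    ("ssc_probands", "insomnia", "target", "DEL", 71, 2.76),
    ("ssc_probands", "insomnia", "other", "DEL", 315, 12.25),
    ("mssng_probands", "circadian", "target", "DUP", 80, 2.43),
    ("mssng_probands", "circadian", "other", "DUP", 953, 28.97),
    ("mssng_probands", "circadian", "target", "DEL", 22, 0.67),
    ("mssng_probands", "circadian", "other", "DEL", 443, 13.47),
    ("mssng_probands", "insomnia", "target", "DUP", 82, 2.49),
    ("mssng_probands", "insomnia", "other", "DUP", 947, 28.79),
    ("mssng_probands", "insomnia", "target", "DEL", 62, 1.88),
    ("mssng_probands", "insomnia", "other", "DEL", 410, 12.47),
    ("ssc_siblings", "circadian", "target", "DUP", 36, 1.72),
    ("ssc_siblings", "circadian", "other", "DUP", 525, 25.09),
    ("ssc_siblings", "circadian", "target", "DEL", 7, 0.33),
    ("ssc_siblings", "circadian", "other", "DEL", 235, 11.23),
    ("ssc_siblings", "insomnia", "target", "DUP", 45, 2.15),
    ("ssc_siblings", "insomnia", "other", "DUP", 519, 24.80),
    ("ssc_siblings", "insomnia", "target", "DEL", 36, 1.72),
    ("ssc_siblings", "insomnia", "other", "DEL", 211, 10.09),
]

# Genome-wide rare CNV events per gene set across all cohorts.
CNV_EVENT_COUNTS = {
    "circadian": {"DUP": 263, "DEL": 72},
    "insomnia": {"DUP": 362, "DEL": 254},
}
CNV_EVENT_TOTALS = {"circadian": 335, "insomnia": 616}


def published_carrier_counts() -> pd.DataFrame:
    """The published carrier-count table with printed percentages.

    The ``consistent`` column marks cells whose printed percentage equals
    round-half-up of 100 * n_carriers / n_total to two decimals.
    """
    from .reporting import carrier_percent

    rows = []
    for cohort, gene_set, side, dosage, k, printed in _CELLS:
        n = COHORT_SIZES[cohort]
        rows.append(
            {
                "cohort": cohort,
                "gene_set": gene_set,
                "side": side,
                "dosage": dosage,
                "n_carriers": k,
                "n_total": n,
                "printed_percent": printed,
                "consistent": carrier_percent(k, n) == printed,
            }
        )
    return pd.DataFrame(rows)
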