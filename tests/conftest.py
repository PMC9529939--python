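import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cnvburden as cb
from cnvburden.annotate import PROFILE_COLUMNS

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome():
    """Default scaled genome shared across tests (seed fixed)."""
    return cb.simulate_genome(seed=42)


@pytest.fixture(scope="session")
def gene_index(genome):
    return cb.GeneIndex(genome.genes)


def make_gene(gene_id, chrom, start, end, loeuf=1.0, ds=0.5, sets=()):
    return cb.GeneRecord(
        gene_id=gene_id,
        interval=cb.GenomicInterval(chrom, start, end),
        loeuf=loeuf,
        ds_score=ds,
        sets=frozenset(sets),
    )


def make_call(chrom, start, end, sample="S1", dosage="DEL", probes=20, cohort="cohort"):
    return cb.CnvCall(
        sample_id=sample,
        interval=cb.GenomicInterval(chrom, start, end),
        dosage=dosage,
        n_probes=probes,
        cohort=cohort,
    )


def profiles_from_carriers(carrier_flags, column="DEL_target_n_genes"):
    """All-zero profiles with `column` set to 1 where carrier_flags is true."""
    n = len(carrier_flags)
    ids = [f"S{i:06d}" for i in range(n)]
    prof = pd.DataFrame(
        0.0, index=pd.Index(ids, name="sample_id"), columns=PROFILE_COLUMNS
    )
    prof.loc[np.asarray(carrier_flags, dtype=bool), column] = 1.0
    return prof


def phenotypes_for(n, **columns):
    base = {"sample_id": [f"S{i:06d}" for i in range(n)], "cohort": "cohort"}
    base.update(columns)
    return pd.DataFrame(base)
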