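"""Gene annotation of CNVs and per-individual dosage burden scores.

Each CNV is intersected with the coding-gene annotation and its gene
content is split into a *target* gene set (circadian, insomnia, or their
union — "sleep genes") and all *other* coding genes. Three burden metrics
are accumulated per side:

* ``n_genes`` — number of genes,
* ``inv_loeuf`` — sum of 1/LOEUF (haploinsufficiency intolerance; a high
  sum marks content strongly intolerant to inactivation),
* ``ds`` — sum of differential-stability brain-expression scores.

Per-individual profiles sum these over all surviving CNVs, stratified by
dosage type (DEL/DUP) x gene set (target/other) — twelve numbers per
person, the design row of every burden regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError
from .intervals import CnvCall, GeneRecord, overlap_bp

logger = logging.getLogger(__name__)

TARGET_SETS = ("circadian", "insomnia", "union")
DOSAGES = ("DEL", "DUP")
SIDES = ("target", "other")
METRICS = ("n_genes", "inv_loeuf", "ds")

PROFILE_COLUMNS = [
    f"{dosage}_{side}_{metric}" for dosage in DOSAGES for side in SIDES for metric in METRICS
]


def in_target(gene: GeneRecord, target_set: str) -> bool:
    if target_set == "union":
        return bool(gene.sets & {"circadian", "insomnia"})
    if target_set in ("circadian", "insomnia"):
        return target_set in gene.sets
    raise ConfigError(f"unknown target set {target_set!r}; expected one of {TARGET_SETS}")


@dataclass(frozen=True)
class SetSums:
    n_genes: int = 0
    inv_loeuf: float = 0.0
    ds: float = 0.0

    def __add__(self, other: "SetSums") -> "SetSums":
        return SetSums(
            self.n_genes + other.n_genes,
            self.inv_loeuf + other.inv_loeuf,
            self.ds + other.ds,
        )


@dataclass(frozen=True)
class AnnotatedCnv:
    """A CNV with its gene content partitioned into target/other sums."""

    call: CnvCall
    gene_ids: tuple[str, ...]
    target: SetSums
    other: SetSums

    @property
    def total_genes(self) -> int:
        return self.target.n_genes + self.other.n_genes

    @property
    def total_inv_loeuf(self) -> float:
        return self.target.inv_loeuf + self.other.inv_loeuf


class GeneIndex:
    """Per-chromosome sorted arrays for fast stabbing queries."""

    def __init__(self, genes: list[GeneRecord]):
        self.genes = list(genes)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[GeneRecord]]] = {}
        for chrom in {g.interval.chrom for g in genes}:
            recs = sorted(
                (g for g in genes if g.interval.chrom == chrom),
                key=lambda g: (g.interval.start, g.interval.end),
            )
            starts = np.array([g.interval.start for g in recs], dtype=np.int64)
            ends = np.array([g.interval.end for g in recs], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, recs)

    def query(self, cnv: CnvCall, rule: str) -> list[GeneRecord]:
        entry = self._by_chrom.get(cnv.interval.chrom)
        if entry is None:
            return []
        starts, ends, recs = entry
        s, e = cnv.interval.start, cnv.interval.end
        if rule == "contained":
            lo = int(np.searchsorted(starts, s, side="left"))
            hi = int(np.searchsorted(starts, e, side="left"))
            return [recs[i] for i in range(lo, hi) if ends[i] <= e]
        if rule == "any_overlap":
            # overlap iff gene.start < e and gene.end > s
            hi = int(np.searchsorted(starts, e, side="left"))
            return [recs[i] for i in range(hi) if ends[i] > s]
        raise ConfigError(f"unknown gene-inclusion rule {rule!r}")


def genes_in_cnv(
    cnv: CnvCall, genes: list[GeneRecord] | GeneIndex, rule: str = "contained"
) -> list[str]:
    """Gene ids intersecting the CNV.

    rule "contained": the gene's full span lies within the CNV ("genes
    encompassed"); "any_overlap": any shared base qualifies.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [g.gene_id for g in index.query(cnv, rule)]


def _sum_records(records: list[GeneRecord]) -> SetSums:
    inv = 0.0
    ds = 0.0
    for g in records:
        if g.loeuf == g.loeuf:
            inv += 1.0 / g.loeuf
        else:
            logger.warning("gene %s has no LOEUF; counted but unscored", g.gene_id)
        if g.ds_score == g.ds_score:
            ds += g.ds_score
        else:
            logger.warning("gene %s has no DS score; counted but unscored", g.gene_id)
    return SetSums(len(records), inv, ds)


def annotate(
    cnv: CnvCall,
    genes: list[GeneRecord] | GeneIndex,
    target_set: str = "union",
    rule: str = "contained",
) -> AnnotatedCnv:
    """Partition a CNV's gene content into target-set and other sums.

    A gene in both circadian and insomnia sets counts once under the union
    target. Genes with missing LOEUF or DS contribute to gene counts but
    not to the corresponding weighted sum.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    hit = index.query(cnv, rule)
    tgt = [g for g in hit if in_target(g, target_set)]
    oth = [g for g in hit if not in_target(g, target_set)]
    return AnnotatedCnv(
        call=cnv,
        gene_ids=tuple(g.gene_id for g in hit),
        target=_sum_records(tgt),
        other=_sum_records(oth),
    )


def annotate_cnvs(
    calls: list[CnvCall],
    genes: list[GeneRecord] | GeneIndex,
    target_set: str = "union",
    rule: str = "contained",
) -> list[AnnotatedCnv]:
    """Annotate a whole call set against one shared gene index."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [annotate(c, index, target_set, rule) for c in calls]


def build_profiles(
    annotated_cnvs: list[AnnotatedCnv], all_samples: list[str]
) -> pd.DataFrame:
    """Per-individual burden profiles, one row per sample (zeros for
    non-carriers), columns ``{DEL,DUP}_{target,other}_{n_genes,inv_loeuf,ds}``.
    """
    sample_ids = [str(s) for s in all_samples]
    known = set(sample_ids)
    orphans = sorted({a.call.sample_id for a in annotated_cnvs} - known)
    if orphans:
        raise ConfigError(f"annotated CNVs reference samples not in the cohort: {orphans}")
    index = pd.Index(sample_ids, name="sample_id")
    if not annotated_cnvs:
        return pd.DataFrame(0.0, index=index, columns=PROFILE_COLUMNS)
    rows = []
    for a in annotated_cnvs:
        d = a.call.dosage
        rows.append(
            {
                "sample_id": a.call.sample_id,
                f"{d}_target_n_genes": a.target.n_genes,
                f"{d}_target_inv_loeuf": a.target.inv_loeuf,
                f"{d}_target_ds": a.target.ds,
                f"{d}_other_n_genes": a.other.n_genes,
                f"{d}_other_inv_loeuf": a.other.inv_loeuf,
                f"{d}_other_ds": a.other.ds,
            }
        )
    contrib = pd.DataFrame(rows).groupby("sample_id").sum()
    prof = contrib.reindex(index=index, columns=PROFILE_COLUMNS, fill_value=0.0).fillna(0.0)
    return prof.astype(float)


def compare_gene_set_scores(
    genes: list[GeneRecord], set_a: str, set_b: str, metric: str = "loeuf"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing a score between two gene sets.

    Returns (U statistic for set_a, p). Used e.g. to show that insomnia
    and circadian genes are skewed toward haploinsufficiency intolerance
    (lower LOEUF) relative to other coding genes.
    """
    from scipy.stats import mannwhitneyu

    if metric not in ("loeuf", "ds"):
        raise ConfigError(f"unknown metric {metric!r}; expected loeuf or ds")

    def values(name: str) -> list[float]:
        if name == "other":
            members = [g for g in genes if not (g.sets & {"circadian", "insomnia"})]
        else:
            members = [g for g in genes if name in g.sets]
        attr = "loeuf" if metric == "loeuf" else "ds_score"
        return [getattr(g, attr) for g in members if getattr(g, attr) == getattr(g, attr)]

    a, b = values(set_a), values(set_b)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"need >= 2 scored genes per set (got {len(a)} in {set_a!r}, {len(b)} in {set_b!r})"
        )
    res = mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
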