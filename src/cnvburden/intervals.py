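"""Genomic interval primitives and the typed records built on them.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
PennCNV-style 1-based inclusive input can be converted at read time (see
:mod:`cnvburden.io_tables`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

_AUTOSOMES = {str(i) for i in range(1, 23)}


def normalize_chrom(name: str, prefix: str = "keep") -> str:
    """Normalize a chromosome name.

    prefix: "keep" leaves the name untouched, "strip" removes a leading
    "chr", "add" ensures one is present.
    """
    name = str(name).strip()
    if prefix == "strip":
        return name[3:] if name.lower().startswith("chr") else name
    if prefix == "add":
        return name if name.lower().startswith("chr") else f"chr{name}"
    if prefix == "keep":
        return name
    raise ValueError(f"unknown chromosome prefix policy: {prefix!r}")


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom, "strip") in _AUTOSOMES


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class CnvCall:
    """One deletion/duplication call in one individual."""

    sample_id: str
    interval: GenomicInterval
    dosage: str  # "DEL" | "DUP"
    n_probes: int = 0
    cohort: str = "cohort"

    def __post_init__(self):
        if self.dosage not in ("DEL", "DUP"):
            raise ValueError(f"dosage must be DEL or DUP, got {self.dosage!r}")
        if self.n_probes < 0:
            raise ValueError("n_probes must be >= 0")


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """A coding gene with its constraint and brain-expression scores.

    loeuf
        Loss-of-function observed/expected upper bound fraction; low values
        mark genes intolerant to haploinsufficiency. May be NaN for unscored
        genes (they still count toward gene numbers).
    ds_score
        Differential-stability brain-expression score in [0, 1]; NaN allowed.
    sets
        Gene-set membership flags, a subset of
        {"circadian", "insomnia", "asd_risk"}.
    """

    gene_id: str
    interval: GenomicInterval
    loeuf: float
    ds_score: float
    sets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.loeuf == self.loeuf and self.loeuf <= 0:  # NaN passes
            raise ValueError(f"gene {self.gene_id}: LOEUF must be > 0")
        if self.ds_score == self.ds_score and not (0.0 <= self.ds_score <= 1.0):
            raise ValueError(f"gene {self.gene_id}: DS score must lie in [0, 1]")
        object.__setattr__(self, "sets", frozenset(self.sets))


@dataclass(frozen=True, slots=True)
class FrequencyPanelEntry:
    """A population CNV frequency record (a DGV-style panel row)."""

    interval: GenomicInterval
    dosage: str
    frequency: float

    def __post_init__(self):
        if self.dosage not in ("DEL", "DUP"):
            raise ValueError(f"dosage must be DEL or DUP, got {self.dosage!r}")
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError("frequency must lie in [0, 1]")


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)) — the CNV-matching convention.

    Both intervals must cover the shared fraction for a high value, so a
    small call inside a huge panel region does not count as a match.
    """
    ov = overlap_bp(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def one_way_overlap(query: GenomicInterval, other: GenomicInterval) -> float:
    """Fraction of *query* covered by *other* (query-only convention)."""
    return overlap_bp(query, other) / query.length


def merge_intervals(regions: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, disjoint list (per chromosome)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for r in ivs[1:]:
            if r.start <= cur_e:
                cur_e = max(cur_e, r.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = r.start, r.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def covered_fraction(target: GenomicInterval, regions: list[GenomicInterval]) -> float:
    """Fraction of *target* bases covered by the union of *regions*.

    The union is taken first so mutually overlapping regions are not
    double-counted.
    """
    if not regions:
        return 0.0
    covered = 0
    for r in merge_intervals([x for x in regions if x.chrom == target.chrom]):
        covered += overlap_bp(target, r)
    return covered / target.length
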