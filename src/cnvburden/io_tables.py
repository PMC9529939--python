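"""Readers and writers for the package's tabular formats.

All files are plain TSV with headers:

* CNV calls: ``chrom  start  end  sample  type  probes  [cohort]``
* genes: ``gene_id  chrom  start  end  loeuf  ds  sets`` (sets semicolon-joined)
* frequency panel: ``chrom  start  end  type  frequency``
* phenotypes: free-form, must contain ``sample_id``
* gene-set lists: one gene symbol per line, ``#`` comments allowed

Row numbers in error messages count data rows from 1 (the header is row 0).
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .errors import SchemaError, ValidationError
from .intervals import (
    CnvCall,
    FrequencyPanelEntry,
    GeneRecord,
    GenomicInterval,
    normalize_chrom,
)

CNV_COLUMNS = ["chrom", "start", "end", "sample", "type", "probes"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "loeuf", "ds", "sets"]
PANEL_COLUMNS = ["chrom", "start", "end", "type", "frequency"]


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    return df


def _check_coords(df: pd.DataFrame, path, one_based: bool) -> pd.DataFrame:
    df = df.copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if one_based:
        # PennCNV-style 1-based inclusive -> 0-based half-open
        df["start"] -= 1
    bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])].tolist()
    if bad:
        rows = [i + 1 for i in bad]
        raise ValidationError(f"{path}: invalid coordinates (start >= end) in rows {rows}", rows)
    return df


def read_cnv_table(path, one_based: bool = False, chrom_prefix: str = "keep") -> list[CnvCall]:
    df = _read_tsv(path, CNV_COLUMNS)
    df = _check_coords(df, path, one_based)
    has_cohort = "cohort" in df.columns
    calls = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            calls.append(
                CnvCall(
                    sample_id=str(row.sample),
                    interval=GenomicInterval(
                        normalize_chrom(row.chrom, chrom_prefix), int(row.start), int(row.end)
                    ),
                    dosage=str(row.type),
                    n_probes=int(row.probes),
                    cohort=str(row.cohort) if has_cohort else "cohort",
                )
            )
        except ValueError as e:
            raise ValidationError(f"{path}: row {i + 1}: {e}", [i + 1]) from e
    return calls


def write_cnv_table(calls: list[CnvCall], path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in calls],
            "start": [c.interval.start for c in calls],
            "end": [c.interval.end for c in calls],
            "sample": [c.sample_id for c in calls],
            "type": [c.dosage for c in calls],
            "probes": [c.n_probes for c in calls],
            "cohort": [c.cohort for c in calls],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_table(path, chrom_prefix: str = "keep") -> list[GeneRecord]:
    df = _read_tsv(path, GENE_COLUMNS)
    df = _check_coords(df, path, one_based=False)
    dup = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate gene ids {sorted(set(dup))}")
    genes = []
    for i, row in enumerate(df.itertuples(index=False)):
        sets = frozenset(
            s for s in str(row.sets).split(";") if s and s not in ("nan", "none", ".")
        )
        try:
            genes.append(
                GeneRecord(
                    gene_id=str(row.gene_id),
                    interval=GenomicInterval(
                        normalize_chrom(row.chrom, chrom_prefix), int(row.start), int(row.end)
                    ),
                    loeuf=float(row.loeuf),
                    ds_score=float(row.ds),
                    sets=sets,
                )
            )
        except ValueError as e:
            raise ValidationError(f"{path}: row {i + 1}: {e}", [i + 1]) from e
    return genes


def write_gene_table(genes: list[GeneRecord], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.interval.chrom for g in genes],
            "start": [g.interval.start for g in genes],
            "end": [g.interval.end for g in genes],
            "loeuf": [g.loeuf for g in genes],
            "ds": [g.ds_score for g in genes],
            "sets": [";".join(sorted(g.sets)) for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_panel(path, chrom_prefix: str = "keep") -> list[FrequencyPanelEntry]:
    df = _read_tsv(path, PANEL_COLUMNS)
    df = _check_coords(df, path, one_based=False)
    entries = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            entries.append(
                FrequencyPanelEntry(
                    interval=GenomicInterval(
                        normalize_chrom(row.chrom, chrom_prefix), int(row.start), int(row.end)
                    ),
                    dosage=str(row.type),
                    frequency=float(row.frequency),
                )
            )
        except ValueError as e:
            raise ValidationError(f"{path}: row {i + 1}: {e}", [i + 1]) from e
    return entries


def write_panel(entries: list[FrequencyPanelEntry], path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [e.interval.chrom for e in entries],
            "start": [e.interval.start for e in entries],
            "end": [e.interval.end for e in entries],
            "type": [e.dosage for e in entries],
            "frequency": [e.frequency for e in entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_tsv(path, ["sample_id"])
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        rows = [i + 1 for i in df.index[df["sample_id"].duplicated()]]
        raise ValidationError(f"{path}: duplicate sample ids in rows {rows}", rows)
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    if "sample_id" not in df.columns:
        raise SchemaError("phenotype table must contain a sample_id column")
    df.to_csv(path, sep="\t", index=False)


def read_gene_set(path) -> set[str]:
    """One gene symbol per line; symbols are uppercased for exact matching."""
    symbols = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.add(line.upper())
    return symbols


def write_gene_set(symbols, path) -> None:
    Path(path).write_text("\n".join(sorted(symbols)) + "\n")


def is_missing(value) -> bool:
    """True for NaN/None/empty/"missing"-style phenotype item entries."""
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip().lower() in ("", "na", "nan", "missing", "none", ".")
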