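"""Genomic file I/O with a single internal coordinate convention.

All coordinates are 0-based half-open (BED-native) everywhere inside the
package.  Chromosome names are matched by exact string equality.  Plain and
gzip-compressed files are both accepted transparently.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Malformed record in a genomic file (carries the 1-based line number)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TagCollection:
    """One sequencing library: mapped-read records plus the per-million total.

    ``total`` is the library-size denominator for all per-million
    normalizations and always equals ``len(records)``.
    """

    records: list[GenomicInterval]
    library_label: str = ""

    def __post_init__(self) -> None:
        for r in self.records:
            if r.strand not in {"+", "-"}:
                raise ValueError(f"tag without strand: {r}")

    @property
    def total(self) -> int:
        return len(self.records)


@dataclass
class ExpressionRecord:
    gene_id: str
    log2fc: float
    pvalue: float | None = None
    fdr: float | None = None

    def __post_init__(self) -> None:
        if self.pvalue is None and self.fdr is None:
            raise ValueError(f"{self.gene_id}: need pvalue or fdr")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _iter_bed_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _parse_bed_fields(fields: list[str], lineno: int, need_strand: bool) -> GenomicInterval:
    if len(fields) < 3:
        raise ParseError(f"line {lineno}: expected >=3 BED fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinate") from exc
    strand = fields[5] if len(fields) >= 6 else "."
    if need_strand and strand not in {"+", "-"}:
        raise ParseError(f"line {lineno}: missing or invalid strand {strand!r}")
    try:
        return GenomicInterval(chrom, start, end, strand)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def read_intervals(path: str | Path, fmt: str = "bed3") -> list[GenomicInterval]:
    """Read a BED3/BED6 file into a sorted list of intervals."""
    if fmt not in {"bed3", "bed6"}:
        raise ValueError(f"unknown format {fmt!r}")
    out = [
        _parse_bed_fields(fields, lineno, need_strand=False)
        for lineno, fields in _iter_bed_lines(path)
    ]
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_tags(path: str | Path, library_label: str = "") -> TagCollection:
    """Read a BED6 tag file; every record must carry a +/- strand."""
    records = [
        _parse_bed_fields(fields, lineno, need_strand=True)
        for lineno, fields in _iter_bed_lines(path)
    ]
    return TagCollection(records=records, library_label=library_label or str(path))


def write_tags(tags: TagCollection, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for i, r in enumerate(tags.records):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\ttag{i}\t0\t{r.strand}\n")


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a TSV expression table (gene_id, log2fc, optional pvalue/fdr).

    Duplicate gene ids are collapsed to the row with the smallest p-value
    (falling back to smallest FDR), with a logged note.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ParseError("expression table lacks a gene_id column")
    if "log2fc" not in df.columns:
        raise ParseError("expression table lacks a log2fc (fold-change) column")
    has_p = "pvalue" in df.columns
    has_fdr = "fdr" in df.columns
    if not has_p and not has_fdr:
        raise ParseError("expression table needs a pvalue or fdr column")
    if df["gene_id"].duplicated().any():
        n_dup = int(df["gene_id"].duplicated().sum())
        log.info("collapsing %d duplicate gene ids to smallest p-value", n_dup)
        key = "pvalue" if has_p else "fdr"
        df = df.sort_values(key, kind="stable").drop_duplicates("gene_id")
        df = df.sort_index()
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ExpressionRecord(
                gene_id=str(row.gene_id),
                log2fc=float(row.log2fc),
                pvalue=float(row.pvalue) if has_p and pd.notna(row.pvalue) else None,
                fdr=float(row.fdr) if has_fdr and pd.notna(row.fdr) else None,
            )
        )
    return out


def write_expression_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    rows = [
        {"gene_id": r.gene_id, "log2fc": r.log2fc, "pvalue": r.pvalue, "fdr": r.fdr}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_sequence(seqs: dict[str, str], interval: GenomicInterval) -> str:
    """Extract the sequence of an interval; minus strand returns the reverse
    complement of the slice."""
    if interval.chrom not in seqs:
        raise KeyError(f"unknown chromosome {interval.chrom!r}")
    seq = seqs[interval.chrom]
    if interval.end > len(seq):
        raise IndexError(
            f"{interval.chrom}:[{interval.start},{interval.end}) beyond "
            f"chromosome end {len(seq)}"
        )
    sub = seq[interval.start : interval.end]
    if interval.strand == "-":
        return reverse_complement(sub)
    return sub


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a TSS TSV (gene_id, chrom, tss, strand); tss is 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"TSS table missing columns: {sorted(missing)}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ParseError(f"TSS table has invalid strands at rows {list(df.index[bad])}")
    return df


def write_tss_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
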